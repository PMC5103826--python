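"""Shared fixtures and seeded random-graph generators."""

from __future__ import annotations

import random

import pytest

from gfakit import GfaGraph, LinkRecord, SegmentRecord, toy_graph
from gfakit.fixtures import TOY_GRAPHS, random_dna


@pytest.fixture(params=TOY_GRAPHS)
def any_toy_graph(request) -> GfaGraph:
    return toy_graph(request.param)


@pytest.fixture
def chain() -> GfaGraph:
    return toy_graph("chain")


@pytest.fixture
def branch() -> GfaGraph:
    return toy_graph("branch")


@pytest.fixture
def bubble() -> GfaGraph:
    return toy_graph("bubble")


def random_graph(rng: random.Random, n_segments: int = 10,
                 n_links: int | None = None) -> GfaGraph:
    """A random GFA graph with sequences and RC tags (no paths)."""
    g = GfaGraph()
    names = [f"s{i}" for i in range(n_segments)]
    for name in names:
        seg = SegmentRecord(name=name, sequence=random_dna(rng.randint(4, 12), rng))
        seg.set_tag("RC", rng.randint(10, 500))
        g.add_record(seg)
    if n_links is None:
        n_links = rng.randint(0, 2 * n_segments)
    for _ in range(n_links):
        a, b = rng.choice(names), rng.choice(names)
        g.add_record(LinkRecord(
            from_name=a, from_orient=rng.choice("+-"),
            to_name=b, to_orient=rng.choice("+-"), overlap="0M"))
    return g


def backbone_graph(rng: random.Random, n_segments: int,
                   n_extra_links: int) -> GfaGraph:
    """A linear-molecule-like graph: a chain backbone with two dead ends
    plus random spurious extra links (the regime the mandatory-link rule
    assumes)."""
    g = GfaGraph()
    names = [f"s{i}" for i in range(n_segments)]
    for name in names:
        g.add_record(SegmentRecord(name=name, sequence=random_dna(6, rng)))
    for a, b in zip(names, names[1:]):
        g.add_record(LinkRecord(from_name=a, from_orient="+",
                                to_name=b, to_orient="+", overlap="0M"))
    for _ in range(n_extra_links):
        a, b = rng.sample(names, 2)
        g.add_record(LinkRecord(
            from_name=a, from_orient=rng.choice("+-"),
            to_name=b, to_orient=rng.choice("+-"), overlap="0M"))
    return g
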