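"""Seeded synthetic data: random DNA, CRISPR loci, toy graph catalogue.

The CRISPR locus generator emulates the geometry of a prokaryotic
CRISPR array: two unique flanks surrounding n instances of one direct
repeat separated by n - 1 unique spacers, optionally with a single-base
substitution at the centre of one repeat instance.  Spacers and flanks
are rejection-sampled so that no canonical (k-1)-mer is shared between
any two of them or with the repeat — the property that makes the de
Bruijn graph of the locus collapse into one repeat unitig plus one
unitig per spacer and flank.

All generators are pure functions of their arguments including the
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from ._sequence import canonical
from .errors import UnknownFixture, UnsatisfiableUniqueness
from .graph import GfaGraph

__all__ = ["random_dna", "CrisprLocusSpec", "make_crispr_locus",
           "toy_graph", "TOY_GRAPHS"]

_BASES = "ACGT"


def random_dna(n: int, seed: int | random.Random) -> str:
    """Uniform random DNA string of length n (deterministic per seed)."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    return "".join(rng.choice(_BASES) for _ in range(n))


@dataclass(frozen=True)
class CrisprLocusSpec:
    """Array geometry: n repeats of one repeat_length-bp repeat separated
    by unique spacer_length-bp spacers, flanked on both sides.

    ``mismatch_at`` (1-based instance index) puts a single substitution
    at the centre of that repeat instance.  ``k`` is the k-mer size the
    locus is destined for; uniqueness is enforced at the (k-1)-mer
    level.
    """

    n_repeats: int = 6
    repeat_length: int = 28
    spacer_length: int = 32
    flank_length: int = 500
    mismatch_at: int | None = None
    seed: int = 0
    k: int = 21

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat instance")
        if self.mismatch_at is not None and not (
                1 <= self.mismatch_at <= self.n_repeats):
            raise ValueError("mismatch_at out of range")

    @property
    def total_length(self) -> int:
        return (2 * self.flank_length + self.n_repeats * self.repeat_length
                + (self.n_repeats - 1) * self.spacer_length)


def _kmers(seq: str, k: int) -> list[str]:
    return [canonical(seq[i:i + k]) for i in range(len(seq) - k + 1)]


def _sample_unique(rng: random.Random, n: int, k: int,
                   used: set[str], attempts: int = 100) -> str:
    """A random n-mer whose canonical (k)-mers are internally distinct
    and disjoint from ``used``; the new k-mers are added to ``used``."""
    for _ in range(attempts):
        cand = random_dna(n, rng)
        kms = _kmers(cand, k) if n >= k else []
        if len(set(kms)) == len(kms) and not (set(kms) & used):
            used.update(kms)
            return cand
    raise UnsatisfiableUniqueness(
        f"could not sample a {n}-mer with unique {k}-mers")


def make_crispr_locus(spec: CrisprLocusSpec) -> str:
    """flank + (repeat + spacer) * (n-1) + repeat + flank, deterministic
    per seed, with (k-1)-mer uniqueness outside the repeat instances."""
    ku = spec.k - 1
    for attempt in range(20):
        rng = random.Random((spec.seed * 1009 + attempt) & 0x7FFFFFFF)
        used: set[str] = set()
        try:
            repeat = _sample_unique(rng, spec.repeat_length, ku, used)
            spacers = [_sample_unique(rng, spec.spacer_length, ku, used)
                       for _ in range(spec.n_repeats - 1)]
            flank_l = _sample_unique(rng, spec.flank_length, ku, used)
            flank_r = _sample_unique(rng, spec.flank_length, ku, used)
        except UnsatisfiableUniqueness:
            continue
        instances = [repeat] * spec.n_repeats
        if spec.mismatch_at is not None:
            centre = (spec.repeat_length - 1) // 2
            old = repeat[centre]
            new = rng.choice([b for b in _BASES if b != old])
            instances[spec.mismatch_at - 1] = (
                repeat[:centre] + new + repeat[centre + 1:])
        parts = [flank_l]
        for i, inst in enumerate(instances):
            parts.append(inst)
            if i < len(spacers):
                parts.append(spacers[i])
        parts.append(flank_r)
        locus = "".join(parts)
        assert len(locus) == spec.total_length
        if _locus_kmers_ok(locus, spec):
            return locus
    raise UnsatisfiableUniqueness(
        "could not satisfy the k-mer uniqueness constraints "
        f"(seed={spec.seed})")


def _locus_kmers_ok(locus: str, spec: CrisprLocusSpec) -> bool:
    """A repeated canonical (k-1)-mer is only acceptable when all of its
    occurrences overlap a repeat instance.

    Windows straddling a repeat boundary legitimately recur when two
    instances share their first or last context bases (unavoidable with
    more instances than alphabet letters); what must never recur is a
    window lying wholly in the flanks or spacers.
    """
    ku = spec.k - 1
    intervals = []
    pos = spec.flank_length
    for _ in range(spec.n_repeats):
        intervals.append((pos, pos + spec.repeat_length))
        pos += spec.repeat_length + spec.spacer_length

    def overlaps_repeat(start: int) -> bool:
        return any(start < b and start + ku > a for a, b in intervals)

    occurrences: dict[str, list[int]] = {}
    for i in range(len(locus) - ku + 1):
        occurrences.setdefault(canonical(locus[i:i + ku]), []).append(i)
    for positions in occurrences.values():
        if len(positions) > 1 and not all(overlaps_repeat(p) for p in positions):
            return False
    return True


# ---------------------------------------------------------------------------
# toy graph catalogue (checked-in GFA text)

TOY_GRAPHS = ("chain", "branch", "bubble", "invertible", "self_loop",
              "two_components")


def toy_graph(name: str) -> GfaGraph:
    """A small hand-written graph from the catalogue: chain (5-segment
    linear path), branch (multiplication/distribution geometry), bubble
    (parallel pair with distinct read counts), invertible, self_loop,
    two_components."""
    if name not in TOY_GRAPHS:
        raise UnknownFixture(
            f"unknown fixture {name!r}; available: {TOY_GRAPHS}")
    text = (resources.files("gfakit") / "data" / "fixtures"
            / f"{name}.gfa").read_text(encoding="utf-8")
    return GfaGraph.from_text(text)
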