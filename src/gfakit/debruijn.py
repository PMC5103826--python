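"""De Bruijn graph construction as a GFA1 graph.

Each distinct canonical k-mer (the lexicographic minimum of a k-mer and
its reverse complement) becomes one segment carrying its total
occurrence count in the KC tag; each observed (k-1)-base overlap
between consecutive k-mers becomes one link with overlap ``(k-1)M``,
with orientations chosen so the link reads through the canonical forms.
Links are deduplicated up to strand flip by the graph container.

k must be odd: an even k admits reverse-complement-palindromic k-mers,
whose segments would be incident to themselves in an ambiguous way.

Merging the linear paths of this graph (see
:func:`gfakit.linear_paths.merge_all_linear_paths`) yields the unitig
graph; for an input without repeated (k-1)-mers the unitigs reassemble
the input sequence exactly (up to reverse complement).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._sequence import DNA_ALPHABET, canonical
from .errors import BadAlphabet, KTooLarge
from .graph import GfaGraph
from .linear_paths import merge_all_linear_paths
from .records import LinkRecord, SegmentRecord

__all__ = ["DeBruijnParams", "build_debruijn_gfa", "unitig_graph"]


@dataclass(frozen=True)
class DeBruijnParams:
    """k-mer size; must be odd and >= 3."""

    k: int = 21

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")


def build_debruijn_gfa(sequences: list[str] | str,
                       params: DeBruijnParams = DeBruijnParams()) -> GfaGraph:
    """Build the canonical-k-mer de Bruijn GFA graph of the inputs.

    Occurrences of a k-mer and of its reverse complement pool into one
    KC count; single-stranded inputs are counted once per occurrence.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    k = params.k
    counts: dict[str, int] = {}
    link_keys: list[tuple[str, str, str, str]] = []
    seen_links: set[tuple] = set()
    for seq in sequences:
        seq = seq.upper()
        if set(seq) - DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise BadAlphabet(f"non-ACGT characters in input: {bad}")
        if len(seq) < k:
            raise KTooLarge(f"sequence length {len(seq)} < k = {k}")
        prev = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            canon = canonical(kmer)
            counts[canon] = counts.get(canon, 0) + 1
            cur = (canon, "+" if kmer == canon else "-")
            if prev is not None:
                key = (prev[0], prev[1], cur[0], cur[1])
                flip = (cur[0], _flip(cur[1]), prev[0], _flip(prev[1]))
                ck = min(key, flip)
                if ck not in seen_links:
                    seen_links.add(ck)
                    link_keys.append(key)
            prev = cur
    graph = GfaGraph()
    names: dict[str, str] = {}
    for idx, canon in enumerate(counts):
        name = f"k{idx}"
        names[canon] = name
        seg = SegmentRecord(name=name, sequence=canon)
        seg.set_tag("KC", counts[canon])
        graph.add_record(seg)
    for a, oa, b, ob in link_keys:
        graph.add_record(LinkRecord(from_name=names[a], from_orient=oa,
                                    to_name=names[b], to_orient=ob,
                                    overlap=f"{k - 1}M"))
    return graph


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def unitig_graph(sequences: list[str] | str,
                 params: DeBruijnParams = DeBruijnParams()) -> GfaGraph:
    """De Bruijn graph with all linear paths merged (tracking enabled);
    KC counts are summed per unitig."""
    graph = build_debruijn_gfa(sequences, params)
    return merge_all_linear_paths(graph, track=True)
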