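"""CRISPR array detection in a merged de Bruijn GFA graph.

A CRISPR locus consists of short conserved direct repeats (24-47 bp)
separated by unique spacers (26-72 bp).  In a de Bruijn graph built
with k smaller than the repeat length the repeat collapses into a
single high-copy-number unitig r, while each spacer forms a unique
unitig that leaves r and comes back to it; the two flanks leave r and
never return.

Detection runs a bounded depth-first traversal from every candidate
repeat segment r with copy number cn(r) > cmin and lrmin <= |r| <=
lrmax.  Path length is measured as |u|, the overlap-trimmed sequence
length of the path excluding r itself: every traversed segment adds its
length and every traversed link (including the links leaving and
re-entering r) subtracts its overlap.  A branch is closed as a

* *circle* when it re-enters r — for a true spacer |u| equals the
  spacer length;
* *terminus* when |u| exceeds |r| + 2 * lsmax, the budget that still
  allows a circle bridging one inexact internal repeat instance
  (|u| = |s_i| + |r| + |s_{i+1}|) but not two.

Each segment is visited at most cn(s) times across the DFS from one
seed.  A candidate is reported when exactly cn(r) - 1 circles and 2
termini are found.  A circle whose |u| exceeds lsmax cannot be a single
spacer and is flagged as bridging a probable inexact repeat instance;
the total instance count is circles + 1 + inexact circles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coverage import CopyNumberParams, CoverageParams, copy_number, segment_coverage
from .ends import OrientedSegment, SegmentEnd, link_between, links_of_end, other_link_end
from .errors import InvalidPath, MissingCopyNumber
from .graph import GfaGraph
from .linear_paths import overlap_length

__all__ = ["CrisprParams", "Circle", "CrisprCandidate", "detect_crisprs",
           "trimmed_path_length"]


@dataclass(frozen=True)
class CrisprParams:
    """Detection thresholds (defaults follow the canonical CRISPR
    geometry: repeats 24-47 bp, spacers 26-72 bp, at least cmin + 1
    repeat instances)."""

    cmin: int = 3
    lrmin: int = 24
    lrmax: int = 47
    lsmin: int = 26
    lsmax: int = 72
    k: int = 21
    scov: float | None = None  # per-k-mer single-copy coverage for cn()

    def __post_init__(self) -> None:
        if self.lrmin > self.lrmax or self.lsmin > self.lsmax:
            raise ValueError("length bounds must satisfy min <= max")
        if self.cmin < 1:
            raise ValueError("cmin must be >= 1")


@dataclass
class Circle:
    """A traversal branch that returned to the seed repeat."""

    path: list[str]  # segment names between the two visits of r
    u_length: int
    inexact: bool


@dataclass
class CrisprCandidate:
    repeat: str
    repeat_length: int
    cn: int
    circles: list[Circle]
    termini: int
    spacer_lengths: list[int] = field(default_factory=list)

    @property
    def inexact_count(self) -> int:
        return sum(1 for c in self.circles if c.inexact)

    @property
    def instance_count(self) -> int:
        return len(self.circles) + 1 + self.inexact_count


def trimmed_path_length(graph: GfaGraph, path: list[OrientedSegment]) -> int:
    """|u| of a path starting at r: sum of non-r segment lengths minus
    the overlaps of every traversed link (r = the first element)."""
    if not path:
        raise InvalidPath("empty path")
    r = path[0].segment
    total = 0
    for prev, cur in zip(path, path[1:]):
        exit_end = SegmentEnd(prev.segment, "E" if prev.orient == "+" else "B")
        entry_end = SegmentEnd(cur.segment, "B" if cur.orient == "+" else "E")
        links = link_between(graph, exit_end, entry_end)
        if not links:
            raise InvalidPath(f"no link between {exit_end} and {entry_end}")
        total -= overlap_length(links[0].overlap)
        if cur.segment != r:
            total += graph.segment_length(cur.segment)
    return total


def _copy_numbers(graph: GfaGraph, params: CrisprParams) -> dict[str, int]:
    cns: dict[str, int] = {}
    cov_params = CoverageParams(count_tag="KC", unit_length=params.k)
    cn_params = (CopyNumberParams(scov=params.scov)
                 if params.scov is not None else None)
    for name, seg in graph.segments.items():
        cn = seg.get_tag("cn")
        if cn is None:
            if cn_params is None:
                raise MissingCopyNumber(
                    f"segment {name!r} has no cn tag and no scov was given")
            cn = copy_number(segment_coverage(seg, cov_params), cn_params)
        cns[name] = cn
    return cns


def detect_crisprs(graph: GfaGraph, params: CrisprParams = CrisprParams()
                   ) -> list[CrisprCandidate]:
    """Report CRISPR candidates found by bounded DFS from every
    qualifying repeat segment (see module docstring)."""
    cns = _copy_numbers(graph, params)
    candidates = []
    for r in sorted(graph.segments):
        len_r = graph.segment_length(r)
        if not (cns[r] > params.cmin and params.lrmin <= len_r <= params.lrmax):
            continue
        budget = len_r + 2 * params.lsmax
        circles: list[Circle] = []
        termini = 0
        visits: dict[str, int] = {}

        def walk(exit_end: SegmentEnd, u_len: int, trail: list[str]) -> None:
            nonlocal termini
            children = sorted(
                links_of_end(graph, exit_end),
                key=lambda l: (other_link_end(l, exit_end).segment,
                               other_link_end(l, exit_end).end_type))
            for link in children:
                t_end = other_link_end(link, exit_end)
                t = t_end.segment
                o = overlap_length(link.overlap)
                if t == r:
                    u = u_len - o
                    circles.append(Circle(path=list(trail), u_length=u,
                                          inexact=u > params.lsmax))
                    continue
                if visits.get(t, 0) >= cns[t]:
                    continue
                u = u_len + graph.segment_length(t) - o
                if u > budget:
                    termini += 1
                    continue
                visits[t] = visits.get(t, 0) + 1
                walk(t_end.other, u, trail + [t])

        for et in "BE":
            walk(SegmentEnd(r, et), 0, [])
        if len(circles) == cns[r] - 1 and termini == 2:
            spacers = [c.u_length for c in circles
                       if params.lsmin <= c.u_length <= params.lsmax]
            candidates.append(CrisprCandidate(
                repeat=r, repeat_length=len_r, cn=cns[r],
                circles=circles, termini=termini, spacer_lengths=spacers))
    return candidates
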