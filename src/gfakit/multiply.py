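"""Copy-number-driven segment multiplication with link distribution.

A segment whose estimated copy number is m > 1 stands for m joined-up
occurrences of the same sequence in the target molecule.  Multiplication
replaces it by m copies, identical except for the count tags (divided by
m, rounding half up).  By default every link of the original is
duplicated onto each copy, which preserves all traversals but multiplies
the link count.

When the copies — and everything reachable from them — are single-copy,
the links of one end can instead be *distributed* over the copies:
with n links L1..Ln on the chosen end and m copies S1..Sm,

* n <= m: Si receives Li (the last m - n copies receive none);
* n >  m: Si receives the run Li..L(i+n-m), i.e. n - m + 1 links each,

which still permits any combination of m of the n links to be used by a
traversal while removing the spurious duplicates.  Links of the other
end are duplicated onto every copy.

Origin tracking records the ancestral segment name in the custom ``or``
tag, so repeated multiplications stay attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .coverage import COUNT_TAGS
from .ends import SegmentEnd, link_ends, links_of_end
from .errors import BadFactor, DistributionPreconditionViolated, UnknownSegment
from .graph import GfaGraph
from .records import LinkRecord

logger = logging.getLogger(__name__)

__all__ = ["MultiplicationSpec", "multiply", "select_distribution_end",
           "plan_distribution"]


@dataclass(frozen=True)
class MultiplicationSpec:
    """How to multiply one segment.

    ``distribution`` is ``"off"`` (duplicate all links), ``"auto"``
    (pick an end heuristically, falling back to duplication), or ``"B"``
    / ``"E"`` (distribute the links of that end).
    """

    segment: str
    factor: int
    distribution: str = "off"
    track_origin: bool = True

    def __post_init__(self) -> None:
        if self.factor < 2:
            raise BadFactor(f"multiplication factor must be >= 2, got {self.factor}")
        if self.distribution not in ("off", "auto", "B", "E"):
            raise ValueError(f"bad distribution {self.distribution!r}")


def plan_distribution(links: list, m: int) -> dict[int, list[int]]:
    """Assignment of link indices (1-based) to copy indices (1-based).

    ``links`` only matters through its length n; the mapping follows the
    run-of-links rule described in the module docstring.
    """
    n = len(links)
    plan: dict[int, list[int]] = {}
    for i in range(1, m + 1):
        if n <= m:
            plan[i] = [i] if i <= n else []
        else:
            plan[i] = list(range(i, i + n - m + 1))
    return plan


def _end_links(graph: GfaGraph, end: SegmentEnd) -> list[LinkRecord]:
    """Links of an end excluding self-links, in the deterministic order
    used for distribution: lexicographic by (other segment, other end)."""
    out = [l for l in links_of_end(graph, end)
           if l.from_name != l.to_name]

    def sort_key(link: LinkRecord):
        e1, e2 = link_ends(link)
        other = e2 if e1 == end else e1
        return (other.segment, other.end_type)

    return sorted(out, key=sort_key)


def select_distribution_end(graph: GfaGraph, segment: str, m: int) -> str | None:
    """Pick the end whose links the distribution should consume.

    An end with fewer than two (non-self) links offers nothing to
    distribute.  A perfect split (lambda = m, one link per copy) is
    preferred; otherwise the end with lambda > m minimising the excess;
    otherwise the eligible end with the largest lambda.  Ties go to E.
    Returns ``None`` when no end is eligible (caller falls back to
    duplication).
    """
    if segment not in graph.segments:
        raise UnknownSegment(f"unknown segment {segment!r}")
    lam = {et: len(_end_links(graph, SegmentEnd(segment, et))) for et in "BE"}
    eligible = [et for et in ("E", "B") if lam[et] >= 2]  # E first on ties
    if not eligible:
        return None
    exact = [et for et in eligible if lam[et] == m]
    if exact:
        return exact[0]
    over = [et for et in eligible if lam[et] > m]
    if over:
        return min(over, key=lambda et: (lam[et] - m, et == "B"))
    return max(eligible, key=lambda et: (lam[et], et == "E"))


def _check_distribution_precondition(graph: GfaGraph, segment: str, m: int) -> None:
    seg = graph.segment(segment)
    cn = seg.get_tag("cn")
    if cn is not None and int(cn / m + 0.5) != 1:
        raise DistributionPreconditionViolated(
            f"segment {segment!r} has cn={cn}; copies would not be single-copy "
            f"after division by {m}")
    # every segment reachable from the copies must be single-copy
    seen = {segment}
    stack = [segment]
    while stack:
        cur = stack.pop()
        for link in graph.links_of_segment(cur):
            for nxt in (link.from_name, link.to_name):
                if nxt not in seen and nxt in graph.segments:
                    seen.add(nxt)
                    stack.append(nxt)
    for name in sorted(seen - {segment}):
        other_cn = graph.segment(name).get_tag("cn")
        if other_cn is None:
            raise DistributionPreconditionViolated(
                f"segment {name!r} reachable from {segment!r} has no cn tag")
        if other_cn != 1:
            raise DistributionPreconditionViolated(
                f"segment {name!r} reachable from {segment!r} has cn={other_cn}")


def _retarget(link: LinkRecord, old: str, new: str) -> LinkRecord:
    clone = link.copy()
    if clone.from_name == old:
        clone.from_name = new
    if clone.to_name == old:
        clone.to_name = new
    return clone


def multiply(graph: GfaGraph, spec: MultiplicationSpec) -> list[str]:
    """Replace a segment by ``factor`` copies; returns the copy names
    (``<name>_c1`` .. ``<name>_cm``)."""
    s = spec.segment
    m = spec.factor
    seg = graph.segment(s)

    dist_end: str | None = None
    if spec.distribution in ("B", "E"):
        dist_end = spec.distribution
    elif spec.distribution == "auto":
        dist_end = select_distribution_end(graph, s, m)
    if dist_end is not None:
        _check_distribution_precondition(graph, s, m)

    self_links = [l for l in graph.links_of_segment(s)
                  if l.from_name == l.to_name == s]
    end_links = {et: _end_links(graph, SegmentEnd(s, et)) for et in "BE"}
    if graph._seg_paths.get(s) or graph._seg_containments.get(s):
        logger.warning(
            "multiplying %r cascades deletion of paths/containments citing it", s)

    graph.delete_segment(s, cascade=True)

    copy_names = [f"{s}_c{i}" for i in range(1, m + 1)]
    origin = seg.get_tag("or") or seg.name
    for name in copy_names:
        clone = seg.copy()
        clone.name = name
        for tag in COUNT_TAGS:
            c = clone.get_tag(tag)
            if c is not None:
                clone.set_tag(tag, int(c / m + 0.5))
        cn = clone.get_tag("cn")
        if cn is not None:
            clone.set_tag("cn", max(1, int(cn / m + 0.5)))
        if spec.track_origin:
            clone.set_tag("or", origin)
        graph.add_record(clone)

    for i, name in enumerate(copy_names, start=1):
        for link in self_links:
            graph.add_record(_retarget(link, s, name))
        for et in "BE":
            if et == dist_end:
                continue
            for link in end_links[et]:
                graph.add_record(_retarget(link, s, name))
    if dist_end is not None:
        plan = plan_distribution(end_links[dist_end], m)
        for i, name in enumerate(copy_names, start=1):
            for j in plan[i]:
                graph.add_record(_retarget(end_links[dist_end][j - 1], s, name))
    return copy_names
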