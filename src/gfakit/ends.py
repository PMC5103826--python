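"""Segment-end algebra.

A GFA segment stands for a double-stranded sequence, so topology is
easiest to reason about in terms of its two *ends* rather than its two
orientations: the B end sits just before the first base of the forward
sequence, the E end just after the last.  Every link touches exactly one
end of each of its two segments:

* the B end collects links *from* the segment in reverse orientation and
  links *to* the segment in forward orientation;
* the E end collects links *from* the segment in forward orientation and
  links *to* the segment in reverse orientation.

All traversal algorithms in this package (linear paths, mandatory links,
CRISPR detection) operate on :class:`SegmentEnd` values.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, NamedTuple

from .errors import NotIncident, UnknownSegment
from .records import LinkRecord

if TYPE_CHECKING:  # pragma: no cover
    from .graph import GfaGraph

__all__ = [
    "SegmentEnd",
    "OrientedSegment",
    "link_ends",
    "links_of_end",
    "end_degree",
    "other_link_end",
    "link_between",
]


class SegmentEnd(NamedTuple):
    segment: str
    end_type: str  # "B" or "E"

    @property
    def other(self) -> "SegmentEnd":
        """The opposite end of the same segment."""
        return SegmentEnd(self.segment, "E" if self.end_type == "B" else "B")

    def __str__(self) -> str:
        return f"{self.segment}{self.end_type}"


class OrientedSegment(NamedTuple):
    segment: str
    orient: str  # "+" or "-"

    @property
    def reverse(self) -> "OrientedSegment":
        return OrientedSegment(self.segment, "-" if self.orient == "+" else "+")

    def __str__(self) -> str:
        return f"{self.segment}{self.orient}"


def link_ends(link: LinkRecord) -> tuple[SegmentEnd, SegmentEnd]:
    """The (from-side, to-side) ends a link is incident to.

    ``from`` with orientation ``+`` uses its E end, with ``-`` its B end;
    ``to`` with ``+`` uses its B end, with ``-`` its E end.
    """
    from_end = SegmentEnd(link.from_name, "E" if link.from_orient == "+" else "B")
    to_end = SegmentEnd(link.to_name, "B" if link.to_orient == "+" else "E")
    return from_end, to_end


def links_of_end(graph: "GfaGraph", end: SegmentEnd) -> list[LinkRecord]:
    """All links incident to a segment end (each link listed once)."""
    if end.segment not in graph.segments:
        raise UnknownSegment(f"unknown segment {end.segment!r}")
    out = []
    for link in graph.links_of_segment(end.segment):
        if end in link_ends(link):
            out.append(link)
    return out


def end_degree(graph: "GfaGraph", end: SegmentEnd) -> int:
    """λ(s, ω): the number of links of the ω end of segment s.

    A self-link touching both ends counts once at each end; a palindromic
    self-link (both incidences on the same end) counts once.
    """
    return len(links_of_end(graph, end))


def other_link_end(link: LinkRecord, end: SegmentEnd) -> SegmentEnd:
    """Given one incident end of a link, return the other incident end."""
    from_end, to_end = link_ends(link)
    if end == from_end:
        return to_end
    if end == to_end:
        return from_end
    raise NotIncident(f"link {link.key()} is not incident to end {end}")


def link_between(graph: "GfaGraph", e1: SegmentEnd, e2: SegmentEnd) -> list[LinkRecord]:
    """Links connecting two specific segment ends."""
    return [l for l in links_of_end(graph, e1) if set(link_ends(l)) == {e1, e2}]
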