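"""Enumeration and merging of maximal linear paths (unitig collapsing).

Write lambda(s, w) for the number of links of end w of segment s.  A
segment with lambda = 1 at both ends is *internal*.  A linear path
starts at a segment whose exit end has a single link, runs through
internal segments, and stops at a segment entered through a single-link
end; such a chain represents one unambiguous stretch of sequence and can
be collapsed into a single segment without losing information.

Merging concatenates the component sequences in traversal orientation
(reverse-complementing segments entered at their E end), trims the
junction overlap bases (n for an ``nM`` junction) from each successor,
sums the count tags, and re-targets the links of the two outer ends onto
the merged segment.  With tracking enabled the merged segment records
its components in the custom ``or`` tag (comma-joined, ``^`` marking a
reverse-complemented component) and their 1-based start offsets in the
``mp`` integer-array tag.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from ._sequence import revcomp
from .coverage import COUNT_TAGS
from .ends import OrientedSegment, SegmentEnd, link_ends, links_of_end, other_link_end
from .errors import InvalidPath, MissingSequence, UnsupportedOverlap
from .graph import GfaGraph
from .records import LinkRecord, SegmentRecord

__all__ = ["LinearPath", "find_linear_paths", "merge_linear_path",
           "merge_all_linear_paths", "overlap_length"]

_NM_RE = re.compile(r"([0-9]+)M\Z")


def overlap_length(overlap: str) -> int:
    """Length of a ``*``/``0M``/``nM`` junction overlap; other CIGARs
    are outside the supported merge semantics."""
    if overlap == "*":
        return 0
    m = _NM_RE.match(overlap)
    if not m:
        raise UnsupportedOverlap(f"cannot merge across overlap {overlap!r}")
    return int(m.group(1))


@dataclass
class LinearPath:
    """An ordered chain of oriented segments with its junction links."""

    items: list[OrientedSegment]
    junctions: list[LinkRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def names(self) -> list[str]:
        return [os.segment for os in self.items]

    def reversed(self) -> "LinearPath":
        return LinearPath([os.reverse for os in reversed(self.items)],
                          list(reversed(self.junctions)))


def _exit_end(os_: OrientedSegment) -> SegmentEnd:
    return SegmentEnd(os_.segment, "E" if os_.orient == "+" else "B")


def _entry_end(os_: OrientedSegment) -> SegmentEnd:
    return SegmentEnd(os_.segment, "B" if os_.orient == "+" else "E")


def find_linear_paths(graph: GfaGraph) -> list[LinearPath]:
    """All maximal linear paths of length >= 2, each reported once.

    A closed cycle of internal segments has no single-link terminus and
    is not reported.
    """
    out: list[LinearPath] = []
    visited: set[str] = set()

    def try_extend(chain: list[OrientedSegment], junctions: list[LinkRecord],
                   forward: bool) -> bool:
        """Extend one step at the tail (forward) or head; returns False
        when the chain cannot grow (or closes into a cycle)."""
        anchor = chain[-1] if forward else chain[0]
        e = _exit_end(anchor) if forward else _entry_end(anchor)
        links = links_of_end(graph, e)
        if len(links) != 1:
            return False
        link = links[0]
        t_end = other_link_end(link, e)
        t = t_end.segment
        if t in {os.segment for os in chain}:
            return False  # cycle: stop without closing
        if len(links_of_end(graph, t_end)) != 1:
            return False  # entered at a branching end: t is a junction hub
        if forward:
            chain.append(OrientedSegment(t, "+" if t_end.end_type == "B" else "-"))
            junctions.append(link)
        else:
            chain.insert(0, OrientedSegment(t, "+" if t_end.end_type == "E" else "-"))
            junctions.insert(0, link)
        return True

    for name in sorted(graph.segments):
        if name in visited:
            continue
        chain = [OrientedSegment(name, "+")]
        junctions: list[LinkRecord] = []
        while try_extend(chain, junctions, forward=True):
            pass
        while try_extend(chain, junctions, forward=False):
            pass
        visited.update(os.segment for os in chain)
        if len(chain) < 2:
            continue
        # a chain whose two outer ends are joined by a single link on
        # each side is a closed cycle, not a linear path
        head_e = _entry_end(chain[0])
        tail_e = _exit_end(chain[-1])
        closing = [l for l in links_of_end(graph, head_e)
                   if set(link_ends(l)) == {head_e, tail_e}]
        if closing and len(links_of_end(graph, head_e)) == 1 \
                and len(links_of_end(graph, tail_e)) == 1:
            continue
        out.append(LinearPath(chain, junctions))
    return out


def _merged_name(tokens: list[str], existing: set[str]) -> str:
    name = "_".join(tokens)
    if len(name) > 80 or name in existing:
        digest = hashlib.md5(name.encode()).hexdigest()[:8]
        name = f"{name[:60]}_{digest}"
    while name in existing:  # pragma: no cover - pathological collision
        name += "x"
    return name


def merge_linear_path(graph: GfaGraph, path: LinearPath, track: bool = True) -> str:
    """Collapse a linear path into one segment; returns its name.

    The merged segment is emitted starting from the endpoint with the
    lexicographically smaller segment name, so output is deterministic
    regardless of where enumeration started.
    """
    if len(path) < 2:
        raise InvalidPath("a linear path to merge needs at least 2 segments")
    for os_ in path.items:
        if os_.segment not in graph.segments:
            raise InvalidPath(f"path cites unknown segment {os_.segment!r}")
    if path.items[-1].segment < path.items[0].segment:
        path = path.reversed()

    comps = [graph.segment(os_.segment) for os_ in path.items]
    trims = [0] + [overlap_length(l.overlap) for l in path.junctions]

    placeholders = [c.sequence == "*" for c in comps]
    if any(placeholders) and not all(placeholders):
        raise MissingSequence(
            "cannot merge a path mixing explicit sequences and '*' placeholders")

    lengths = [graph.segment_length(c.name) for c in comps]
    starts: list[int] = []
    pos = 1
    for length, trim in zip(lengths, trims):
        if trim >= length:
            raise UnsupportedOverlap(
                f"junction overlap {trim} consumes a whole {length} bp segment")
        starts.append(pos)
        pos += length - trim
    merged_length = pos - 1

    if all(placeholders):
        merged_seq = "*"
    else:
        parts = []
        for os_, comp, trim in zip(path.items, comps, trims):
            seq = comp.sequence if os_.orient == "+" else revcomp(comp.sequence)
            parts.append(seq[trim:])
        merged_seq = "".join(parts)
        assert len(merged_seq) == merged_length

    tokens = [os_.segment + ("" if os_.orient == "+" else "^")
              for os_ in path.items]
    existing = set(graph.segments) - {os_.segment for os_ in path.items}
    name = _merged_name(tokens, existing)

    merged = SegmentRecord(name=name, sequence=merged_seq)
    for tag in COUNT_TAGS:
        vals = [c.get_tag(tag) for c in comps]
        present = [v for v in vals if v is not None]
        if present:
            merged.set_tag(tag, sum(present))
    if merged_seq == "*":
        merged.set_tag("LN", merged_length)
    if track:
        merged.set_tag("or", ",".join(tokens))
        merged.set_tag("mp", starts)

    # collect external links of the two outer ends before deletion
    first_outer = _entry_end(path.items[0])
    last_outer = _exit_end(path.items[-1])
    internal = set(path.junctions)
    ext: list[LinkRecord] = []
    for outer in (first_outer, last_outer):
        for link in links_of_end(graph, outer):
            if link not in internal and link not in ext:
                ext.append(link)

    retargeted = []
    for link in ext:
        e1, e2 = link_ends(link)

        def remap(e: SegmentEnd) -> SegmentEnd:
            if e == first_outer:
                return SegmentEnd(name, "B")
            if e == last_outer:
                return SegmentEnd(name, "E")
            return e

        n1, n2 = remap(e1), remap(e2)
        clone = link.copy()
        clone.from_name = n1.segment
        clone.from_orient = "+" if n1.end_type == "E" else "-"
        clone.to_name = n2.segment
        clone.to_orient = "+" if n2.end_type == "B" else "-"
        retargeted.append(clone)

    for os_ in path.items:
        graph.delete_segment(os_.segment, cascade=True)
    graph.add_record(merged)
    for link in retargeted:
        graph.add_record(link)
    return name


def merge_all_linear_paths(graph: GfaGraph, track: bool = True) -> GfaGraph:
    """Merge until no linear path of length >= 2 remains (fixed point)."""
    while True:
        paths = find_linear_paths(graph)
        if not paths:
            return graph
        for path in paths:
            merge_linear_path(graph, path, track=track)
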