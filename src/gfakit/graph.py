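"""In-memory GFA1 graph: indexed records, reference integrity, I/O, stats.

Segments and paths are indexed by name; links and containments keep
per-segment reference lists so that the links of a segment (or of one of
its ends, see :mod:`gfakit.ends`) can be enumerated without scanning the
whole graph.  References may be added before the segments they cite
(deferred resolution); :func:`GfaGraph.validate_references` reports any
name that never resolved.

A link and its reverse-complement form (from/to swapped, both
orientations flipped) describe the same double-stranded junction and are
stored once.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .errors import (
    DanglingReferences,
    DuplicateName,
    MissingLength,
    ParseError,
    UnknownName,
    UnknownSegment,
)
from .records import (
    ContainmentRecord,
    GfaRecord,
    HeaderRecord,
    LinkRecord,
    OpaqueRecord,
    PathRecord,
    SegmentRecord,
    parse_record,
)

logger = logging.getLogger(__name__)

__all__ = ["GfaGraph", "GraphInfo", "read_gfa", "write_gfa", "link_flip_key"]


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def link_flip_key(link: LinkRecord) -> tuple:
    """Canonical link key, invariant under reverse-complement rewriting."""
    fwd = (link.from_name, link.from_orient, link.to_name, link.to_orient)
    rev = (link.to_name, _flip(link.to_orient),
           link.from_name, _flip(link.from_orient))
    return (min(fwd, rev), link.overlap)


@dataclass
class GraphInfo:
    """Topology and sequence-length summary of a graph."""

    n_segments: int
    n_links: int
    n_connected_components: int
    n_dead_ends: int
    total_length: int
    longest: int
    shortest: int
    average: float
    n50: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class GfaGraph:
    """A GFA1 graph: headers, named segments/paths, links, containments."""

    def __init__(self) -> None:
        self.headers: list[HeaderRecord] = []
        self.segments: dict[str, SegmentRecord] = {}
        self.links: list[LinkRecord] = []
        self.containments: list[ContainmentRecord] = []
        self.paths: dict[str, PathRecord] = {}
        self.opaque: list[OpaqueRecord] = []
        self._link_keys: set[tuple] = set()
        self._seg_links: dict[str, list[LinkRecord]] = {}
        self._seg_containments: dict[str, list[ContainmentRecord]] = {}
        self._seg_paths: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    def add_record(self, rec: GfaRecord) -> "GfaGraph":
        """Index one record.  Raises :class:`DuplicateName` for a segment
        or path whose name is already present; a link equal to a stored
        one up to reverse complement is ignored."""
        if isinstance(rec, HeaderRecord):
            vn = rec.get_tag("VN")
            if vn is not None and vn != "1.0":
                logger.warning("GFA version %r declared; this library targets 1.0", vn)
            self.headers.append(rec)
        elif isinstance(rec, SegmentRecord):
            if rec.name in self.segments:
                raise DuplicateName(f"duplicate segment name {rec.name!r}")
            self.segments[rec.name] = rec
        elif isinstance(rec, LinkRecord):
            key = link_flip_key(rec)
            if key in self._link_keys:
                logger.debug("duplicate link %s ignored", rec.key())
                return self
            self._link_keys.add(key)
            self.links.append(rec)
            self._seg_links.setdefault(rec.from_name, []).append(rec)
            if rec.to_name != rec.from_name:
                self._seg_links.setdefault(rec.to_name, []).append(rec)
        elif isinstance(rec, ContainmentRecord):
            self.containments.append(rec)
            self._seg_containments.setdefault(rec.from_name, []).append(rec)
            if rec.to_name != rec.from_name:
                self._seg_containments.setdefault(rec.to_name, []).append(rec)
        elif isinstance(rec, PathRecord):
            if rec.name in self.paths:
                raise DuplicateName(f"duplicate path name {rec.name!r}")
            self.paths[rec.name] = rec
            for seg, _ in rec.segment_names:
                self._seg_paths.setdefault(seg, set()).add(rec.name)
        elif isinstance(rec, OpaqueRecord):
            self.opaque.append(rec)
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot add {type(rec).__name__}")
        return self

    def add_line(self, line: str) -> "GfaGraph":
        return self.add_record(parse_record(line))

    # -- accessors ----------------------------------------------------

    def segment(self, name: str) -> SegmentRecord:
        try:
            return self.segments[name]
        except KeyError:
            raise UnknownSegment(f"unknown segment {name!r}") from None

    def links_of_segment(self, name: str) -> list[LinkRecord]:
        return list(self._seg_links.get(name, []))

    def containments_of_segment(self, name: str) -> list[ContainmentRecord]:
        return list(self._seg_containments.get(name, []))

    def paths_of_segment(self, name: str) -> list[PathRecord]:
        return [self.paths[p] for p in sorted(self._seg_paths.get(name, set()))
                if p in self.paths]

    def records(self) -> Iterator[GfaRecord]:
        yield from self.headers
        yield from self.segments.values()
        yield from self.links
        yield from self.containments
        yield from self.paths.values()
        yield from self.opaque

    def segment_length(self, name: str) -> int:
        seg = self.segment(name)
        length = seg.length
        if length is None:
            raise MissingLength(f"segment {name!r} has no sequence and no LN tag")
        return length

    def copy(self) -> "GfaGraph":
        g = GfaGraph()
        for rec in self.records():
            g.add_record(rec.copy())
        return g

    # -- deletion -----------------------------------------------------

    def delete_link(self, link: LinkRecord) -> "GfaGraph":
        self.links.remove(link)
        self._link_keys.discard(link_flip_key(link))
        for name in {link.from_name, link.to_name}:
            lst = self._seg_links.get(name)
            if lst and link in lst:
                lst.remove(link)
        return self

    def delete_containment(self, cont: ContainmentRecord) -> "GfaGraph":
        self.containments.remove(cont)
        for name in {cont.from_name, cont.to_name}:
            lst = self._seg_containments.get(name)
            if lst and cont in lst:
                lst.remove(cont)
        return self

    def delete_path(self, name: str) -> "GfaGraph":
        rec = self.paths.pop(name, None)
        if rec is not None:
            for seg, _ in rec.segment_names:
                self._seg_paths.get(seg, set()).discard(name)
        return self

    def delete_segment(self, name: str, cascade: bool = True) -> "GfaGraph":
        """Remove a segment; by default the deletion cascades to every
        link, containment and path referring to it."""
        if name not in self.segments:
            raise UnknownSegment(f"unknown segment {name!r}")
        refs = (self._seg_links.get(name, []) or
                self._seg_containments.get(name, []) or
                self._seg_paths.get(name, set()))
        if refs and not cascade:
            raise DanglingReferences(
                f"segment {name!r} is referenced; delete with cascade=True")
        for link in list(self._seg_links.get(name, [])):
            self.delete_link(link)
        for cont in list(self._seg_containments.get(name, [])):
            self.delete_containment(cont)
        for pname in list(self._seg_paths.get(name, set())):
            self.delete_path(pname)
        del self.segments[name]
        self._seg_links.pop(name, None)
        self._seg_containments.pop(name, None)
        self._seg_paths.pop(name, None)
        return self

    # -- renaming -----------------------------------------------------

    def rename(self, old: str, new: str) -> "GfaGraph":
        """Rename a segment or a path; all references are updated."""
        if old in self.segments:
            if new in self.segments:
                raise DuplicateName(f"segment name {new!r} already in use")
            seg = self.segments.pop(old)
            seg.name = new
            self.segments[new] = seg
            for link in self._seg_links.pop(old, []):
                if link.from_name == old:
                    link.from_name = new
                if link.to_name == old:
                    link.to_name = new
                self._seg_links.setdefault(new, []).append(link)
            self._link_keys = {link_flip_key(l) for l in self.links}
            for cont in self._seg_containments.pop(old, []):
                if cont.from_name == old:
                    cont.from_name = new
                if cont.to_name == old:
                    cont.to_name = new
                self._seg_containments.setdefault(new, []).append(cont)
            for pname in self._seg_paths.pop(old, set()):
                path = self.paths[pname]
                path.segment_names = [
                    (new if n == old else n, o) for n, o in path.segment_names]
                self._seg_paths.setdefault(new, set()).add(pname)
        elif old in self.paths:
            if new in self.paths:
                raise DuplicateName(f"path name {new!r} already in use")
            path = self.paths.pop(old)
            path.name = new
            self.paths[new] = path
            for seg, _ in path.segment_names:
                refs = self._seg_paths.get(seg, set())
                refs.discard(old)
                refs.add(new)
        else:
            raise UnknownName(f"no segment or path named {old!r}")
        return self

    # -- validation ---------------------------------------------------

    def validate_references(self) -> list[str]:
        """One violation per unresolved name and per path junction with
        no matching link (checked in both strand representations)."""
        v: list[str] = []
        for link in self.links:
            for nm in (link.from_name, link.to_name):
                if nm not in self.segments:
                    v.append(f"link {link.key()} cites unknown segment {nm!r}")
        for cont in self.containments:
            for nm in (cont.from_name, cont.to_name):
                if nm not in self.segments:
                    v.append(f"containment {cont.key()} cites unknown segment {nm!r}")
        for path in self.paths.values():
            for nm, _ in path.segment_names:
                if nm not in self.segments:
                    v.append(f"path {path.name!r} cites unknown segment {nm!r}")
            for (a, oa), (b, ob) in zip(path.segment_names, path.segment_names[1:]):
                fwd = (a, oa, b, ob)
                rev = (b, _flip(ob), a, _flip(oa))
                found = any(
                    (l.from_name, l.from_orient, l.to_name, l.to_orient) in (fwd, rev)
                    for l in self._seg_links.get(a, []))
                if not found:
                    v.append(f"path {path.name!r}: no link supports junction "
                             f"{a}{oa} -> {b}{ob}")
        return v

    # -- statistics ---------------------------------------------------

    def info(self) -> GraphInfo:
        """Counts, connected components, dead ends and length statistics.

        Components are computed on the undirected segment adjacency
        induced by links only; a dead end is a segment end with no link,
        so an isolated segment contributes two.
        """
        lengths = [self.segment_length(n) for n in self.segments]
        n_seg = len(self.segments)
        parent = {name: name for name in self.segments}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        end_deg: dict[tuple[str, str], int] = {}
        from .ends import link_ends  # local import avoids a cycle

        for link in self.links:
            e1, e2 = link_ends(link)
            for e in {e1, e2}:  # palindromic self-link counted once
                end_deg[e] = end_deg.get(e, 0) + 1
            if link.from_name in parent and link.to_name in parent:
                ra, rb = find(link.from_name), find(link.to_name)
                if ra != rb:
                    parent[ra] = rb
        n_components = len({find(n) for n in self.segments})
        n_dead = sum(1 for name in self.segments for et in "BE"
                     if end_deg.get((name, et), 0) == 0)
        total = sum(lengths)
        n50 = 0
        if lengths:
            acc = 0
            for length in sorted(lengths, reverse=True):
                acc += length
                if 2 * acc >= total:
                    n50 = length
                    break
        return GraphInfo(
            n_segments=n_seg,
            n_links=len(self.links),
            n_connected_components=n_components,
            n_dead_ends=n_dead,
            total_length=total,
            longest=max(lengths, default=0),
            shortest=min(lengths, default=0),
            average=(total / n_seg) if n_seg else math.nan,
            n50=n50,
        )

    # -- text I/O -----------------------------------------------------

    @classmethod
    def from_lines(cls, lines: Iterable[str], strict: bool = False,
                   lenient: bool = False) -> "GfaGraph":
        g = cls()
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue  # empty lines can be ignored
            try:
                g.add_record(parse_record(line))
            except ParseError as exc:
                if lenient:
                    logger.warning("line %d unparseable, stored verbatim: %s",
                                   lineno, exc)
                    g.add_record(OpaqueRecord(text=line))
                else:
                    raise ParseError(f"line {lineno}: {exc}") from exc
        if strict:
            violations = g.validate_references()
            if violations:
                raise UnknownName("; ".join(violations))
        return g

    @classmethod
    def from_text(cls, text: str, **kwargs) -> "GfaGraph":
        return cls.from_lines(text.splitlines(), **kwargs)

    def to_text(self) -> str:
        return "".join(rec.render() + "\n" for rec in self.records())


Source = Union[str, Path, IO[str]]


def read_gfa(source: Source, strict: bool = False, lenient: bool = False) -> GfaGraph:
    """Read a GFA1 graph from a path, an open text stream or ``"-"`` (stdin)."""
    if isinstance(source, (str, Path)):
        if source == "-":
            import sys

            return GfaGraph.from_lines(sys.stdin, strict=strict, lenient=lenient)
        with open(source, encoding="utf-8") as fh:
            return GfaGraph.from_lines(fh, strict=strict, lenient=lenient)
    return GfaGraph.from_lines(source, strict=strict, lenient=lenient)


def write_gfa(graph: GfaGraph, dest: Source | None = None) -> str:
    """Write a graph as GFA1 text; returns the text, optionally writing
    it to a path or stream (``"-"`` writes to stdout)."""
    text = graph.to_text()
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        if dest == "-":
            import sys

            sys.stdout.write(text)
        else:
            Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)
    return text
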