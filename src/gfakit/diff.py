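"""Semantic comparison of two GFA graphs and replayable edit scripts.

A GFA file is line-oriented text, but a textual diff is too strict:
record order, tag order, float formatting, JSON whitespace and the
strand in which a link is written are all meaningless variation.  This
module compares two graphs at field granularity:

* headers as one multiset of tags pooled over all H lines;
* segments and paths matched by name, then compared field by field and
  tag by tag;
* links matched by their key up to reverse-complement rewriting;
* containments matched by their exact key (the strand-flipped form of a
  containment cannot be computed without sequence lengths).

The difference can be rendered as a diff-style report, or emitted as a
line-delimited *edit script* whose replay transforms the first graph
into one semantically equal to the second.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ScriptTargetMissing
from .graph import GfaGraph, link_flip_key
from .records import (
    ContainmentRecord,
    GfaRecord,
    HeaderRecord,
    LinkRecord,
    PathRecord,
    SegmentRecord,
    Tag,
    parse_record,
)

__all__ = ["DiffReport", "Change", "diff_graphs", "render_report",
           "emit_edit_script", "apply_edit_script", "graphs_equal"]


@dataclass(frozen=True)
class Change:
    """One field- or tag-level difference of records matched by identity.

    ``ident`` is the record name (S/P), the link/containment key fields
    joined by spaces (L/C), or empty for the pooled header tags.  For a
    tag difference ``old``/``new`` may be None (tag absent on one side).
    """

    code: str
    ident: str
    field: str
    old: str | None
    new: str | None


@dataclass
class DiffReport:
    added: list[GfaRecord] = field(default_factory=list)
    removed: list[GfaRecord] = field(default_factory=list)
    changes: list[Change] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.added or self.removed or self.changes)


def _tag_map(rec: GfaRecord) -> dict[str, Tag]:
    return dict(rec.tags)


def _diff_tags(code: str, ident: str, t1: dict[str, Tag], t2: dict[str, Tag],
               out: list[Change]) -> None:
    for name in sorted(set(t1) | set(t2)):
        a, b = t1.get(name), t2.get(name)
        if a == b:
            continue
        out.append(Change(code, ident, name,
                          a.render() if a else None,
                          b.render() if b else None))


def _link_ident(link: LinkRecord) -> str:
    return " ".join(str(x) for x in link.key())


def _cont_ident(cont: ContainmentRecord) -> str:
    return " ".join(str(x) for x in cont.key())


def diff_graphs(g1: GfaGraph, g2: GfaGraph) -> DiffReport:
    """Field-granular semantic difference between two graphs."""
    rep = DiffReport()

    # headers: pooled multiset of canonical tag texts
    def header_tags(g: GfaGraph) -> Counter:
        return Counter(t.render() for h in g.headers for t in h.tags.values())

    h1, h2 = header_tags(g1), header_tags(g2)
    for text in sorted((h1 - h2).elements()):
        rep.changes.append(Change("H", "", text.split(":", 1)[0], text, None))
    for text in sorted((h2 - h1).elements()):
        rep.changes.append(Change("H", "", text.split(":", 1)[0], None, text))

    # segments by name
    for name in sorted(set(g1.segments) | set(g2.segments)):
        a, b = g1.segments.get(name), g2.segments.get(name)
        if a is None:
            rep.added.append(b)
        elif b is None:
            rep.removed.append(a)
        else:
            if a.sequence != b.sequence:
                rep.changes.append(Change("S", name, "sequence",
                                          a.sequence, b.sequence))
            _diff_tags("S", name, _tag_map(a), _tag_map(b), rep.changes)

    # paths by name
    for name in sorted(set(g1.paths) | set(g2.paths)):
        a, b = g1.paths.get(name), g2.paths.get(name)
        if a is None:
            rep.added.append(b)
        elif b is None:
            rep.removed.append(a)
        else:
            sa, sb = a._positional()[1], b._positional()[1]
            if sa != sb:
                rep.changes.append(Change("P", name, "segment_names", sa, sb))
            oa, ob = a._positional()[2], b._positional()[2]
            if oa != ob:
                rep.changes.append(Change("P", name, "overlaps", oa, ob))
            _diff_tags("P", name, _tag_map(a), _tag_map(b), rep.changes)

    # links up to reverse-complement identity
    l1 = {link_flip_key(l): l for l in g1.links}
    l2 = {link_flip_key(l): l for l in g2.links}
    for key in sorted(set(l1) | set(l2), key=repr):
        a, b = l1.get(key), l2.get(key)
        if a is None:
            rep.added.append(b)
        elif b is None:
            rep.removed.append(a)
        else:
            _diff_tags("L", _link_ident(a), _tag_map(a), _tag_map(b), rep.changes)

    # containments by exact key
    c1 = Counter()
    c2 = Counter()
    rep1 = {}
    rep2 = {}
    for c in g1.containments:
        c1[c.key()] += 1
        rep1[c.key()] = c
    for c in g2.containments:
        c2[c.key()] += 1
        rep2[c.key()] = c
    for key in sorted(set(c1) | set(c2), key=repr):
        n1, n2 = c1[key], c2[key]
        for _ in range(max(0, n1 - n2)):
            rep.removed.append(rep1[key])
        for _ in range(max(0, n2 - n1)):
            rep.added.append(rep2[key])
        if n1 and n2:
            _diff_tags("C", _cont_ident(rep1[key]),
                       _tag_map(rep1[key]), _tag_map(rep2[key]), rep.changes)
    return rep


def graphs_equal(g1: GfaGraph, g2: GfaGraph) -> bool:
    return diff_graphs(g1, g2).empty


def render_report(report: DiffReport) -> str:
    """diff(1)-style text: ``<`` removed, ``>`` added, ``|`` changed."""
    lines = []
    for rec in report.removed:
        lines.append(f"< {rec.render()}")
    for rec in report.added:
        lines.append(f"> {rec.render()}")
    for ch in report.changes:
        old = ch.old if ch.old is not None else "-"
        new = ch.new if ch.new is not None else "-"
        ident = ch.ident or "-"
        lines.append(f"| {ch.code} {ident} {ch.field} {old} {new}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# edit scripts: one tab-separated edit per line


def _del_fields(rec: GfaRecord) -> list[str]:
    if isinstance(rec, SegmentRecord):
        return ["S", rec.name]
    if isinstance(rec, PathRecord):
        return ["P", rec.name]
    if isinstance(rec, LinkRecord):
        return ["L", *[str(x) for x in rec.key()]]
    if isinstance(rec, ContainmentRecord):
        return ["C", *[str(x) for x in rec.key()]]
    raise TypeError(type(rec).__name__)  # pragma: no cover


def emit_edit_script(report: DiffReport) -> list[str]:
    """Serialize a diff as replayable edit lines (see apply_edit_script).

    Record deletions come first so that a delete/re-add of the same name
    replays cleanly.
    """
    lines: list[str] = []
    # delete links/containments/paths before segments: deleting a segment
    # cascades, which would orphan later deletions of its edges
    order = {"L": 0, "C": 1, "P": 2, "S": 3}
    for rec in sorted(report.removed, key=lambda r: order.get(r.code, 4)):
        lines.append("\t".join(["del"] + _del_fields(rec)))
    for rec in report.added:
        lines.append("add\t" + rec.render())
    for ch in report.changes:
        if ch.code == "H":
            if ch.new is None:
                lines.append(f"del_htag\t{ch.old}")
            else:
                lines.append(f"add_htag\t{ch.new}")
            continue
        ident = ch.ident.split(" ") if ch.ident else []
        if ch.field in ("sequence", "segment_names", "overlaps"):
            lines.append("\t".join(["set_field", ch.code, *ident,
                                    ch.field, ch.new]))
        elif ch.new is None:
            lines.append("\t".join(["del_tag", ch.code, *ident, ch.field]))
        else:
            lines.append("\t".join(["set_tag", ch.code, *ident, ch.new]))
    return lines


def _find_link(graph: GfaGraph, key_fields: list[str]) -> LinkRecord:
    probe = LinkRecord(from_name=key_fields[0], from_orient=key_fields[1],
                       to_name=key_fields[2], to_orient=key_fields[3],
                       overlap=key_fields[4])
    want = link_flip_key(probe)
    for link in graph.links:
        if link_flip_key(link) == want:
            return link
    raise ScriptTargetMissing(f"no link {key_fields} in target graph")


def _find_containment(graph: GfaGraph, key_fields: list[str]) -> ContainmentRecord:
    key = (key_fields[0], key_fields[1], key_fields[2], key_fields[3],
           int(key_fields[4]), key_fields[5])
    for cont in graph.containments:
        if cont.key() == key:
            return cont
    raise ScriptTargetMissing(f"no containment {key_fields} in target graph")


def _target(graph: GfaGraph, code: str, fields: list[str]) -> tuple[GfaRecord, list[str]]:
    """Resolve (record, remaining fields) for an edit line body."""
    if code == "S":
        name = fields[0]
        if name not in graph.segments:
            raise ScriptTargetMissing(f"no segment {name!r} in target graph")
        return graph.segments[name], fields[1:]
    if code == "P":
        name = fields[0]
        if name not in graph.paths:
            raise ScriptTargetMissing(f"no path {name!r} in target graph")
        return graph.paths[name], fields[1:]
    if code == "L":
        return _find_link(graph, fields[:5]), fields[5:]
    if code == "C":
        return _find_containment(graph, fields[:6]), fields[6:]
    raise ScriptTargetMissing(f"bad record code {code!r} in edit script")


def apply_edit_script(graph: GfaGraph, script: list[str]) -> GfaGraph:
    """Replay an edit script in place; returns the graph.

    Raises :class:`ScriptTargetMissing` when an edit cites a record the
    graph does not contain.
    """
    for line in script:
        line = line.rstrip("\n")
        if not line:
            continue
        op, *fields = line.split("\t")
        if op == "add":
            graph.add_record(parse_record("\t".join(fields)))
        elif op == "del":
            code = fields[0]
            if code == "S":
                if fields[1] not in graph.segments:
                    raise ScriptTargetMissing(f"no segment {fields[1]!r} to delete")
                graph.delete_segment(fields[1], cascade=True)
            elif code == "P":
                if fields[1] not in graph.paths:
                    raise ScriptTargetMissing(f"no path {fields[1]!r} to delete")
                graph.delete_path(fields[1])
            elif code == "L":
                graph.delete_link(_find_link(graph, fields[1:6]))
            elif code == "C":
                graph.delete_containment(_find_containment(graph, fields[1:7]))
            else:
                raise ScriptTargetMissing(f"bad record code {code!r}")
        elif op == "set_field":
            rec, rest = _target(graph, fields[0], fields[1:])
            fname, value = rest[0], rest[1] if len(rest) > 1 else ""
            if fname == "sequence":
                rec.sequence = value  # type: ignore[attr-defined]
            elif fname == "segment_names":
                rec.segment_names = [(item[:-1], item[-1])  # type: ignore
                                     for item in value.split(",")]
            elif fname == "overlaps":
                rec.overlaps = None if value == "*" else value.split(",")  # type: ignore
            else:
                raise ScriptTargetMissing(f"unknown field {fname!r}")
        elif op == "set_tag":
            rec, rest = _target(graph, fields[0], fields[1:])
            tag = Tag.parse(rest[0])
            rec.tags[tag.name] = tag
        elif op == "del_tag":
            rec, rest = _target(graph, fields[0], fields[1:])
            rec.delete_tag(rest[0])
        elif op == "del_htag":
            tag = Tag.parse(fields[0])
            for header in graph.headers:
                if header.tags.get(tag.name) == tag:
                    header.delete_tag(tag.name)
                    break
            else:
                raise ScriptTargetMissing(f"no header tag {fields[0]!r}")
        elif op == "add_htag":
            tag = Tag.parse(fields[0])
            if graph.headers and tag.name not in graph.headers[0].tags:
                graph.headers[0].tags[tag.name] = tag
            else:
                graph.add_record(HeaderRecord(tags={tag.name: tag}))
        else:
            raise ScriptTargetMissing(f"unknown edit op {op!r}")
    return graph
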