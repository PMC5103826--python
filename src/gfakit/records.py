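"""Parsing, validation and rendering of single GFA1 lines.

A GFA1 file is a tab-separated, line-oriented text format closely related
to SAM.  Each line starts with a single capital letter giving the record
type — H (header), S (segment), L (link), C (containment) or P (path) —
followed by the type's required positional fields and then any number of
optional typed tags of the form ``NN:T:value``.

Tag datatypes follow the SAM convention: A (single printable character),
i (signed integer), f (float), Z (printable string), J (JSON), H (hex byte
array) and B (numeric array with a subtype code in ``cCsSiIf``).  Values
are converted to and from native Python objects (``int``, ``float``,
``str``, ``list``, JSON trees) on access.

Equality of records ignores tag order; insertion order is preserved when
rendering.  J-typed tags are compared structurally, f-typed tags
numerically, so formatting differences (``1.0`` vs ``1.00``, JSON
whitespace) are invisible to comparison.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterable

from .errors import (
    InvalidTagName,
    MalformedTag,
    MissingRequiredField,
    TypeMismatch,
    UnknownRecordType,
)

__all__ = [
    "Tag",
    "GfaRecord",
    "HeaderRecord",
    "SegmentRecord",
    "LinkRecord",
    "ContainmentRecord",
    "PathRecord",
    "OpaqueRecord",
    "parse_record",
    "render_record",
]

# Field-content regular expressions (anchored on use).
TAG_NAME_RE = re.compile(r"[a-zA-Z][a-zA-Z0-9]\Z")
SEGMENT_NAME_RE = re.compile(r"[!-)+-<>-~][!-~]*\Z")
ORIENT_RE = re.compile(r"[+-]\Z")
OVERLAP_RE = re.compile(r"\*|([0-9]+[MIDNSHPX=])+\Z")
POS_RE = re.compile(r"[0-9]+\Z")
SEQUENCE_RE = re.compile(r"\*|[A-Za-z=.]+\Z")

TAG_VALUE_RE = {
    "A": re.compile(r"[!-~]\Z"),
    "i": re.compile(r"[-+]?[0-9]+\Z"),
    "f": re.compile(r"[-+]?[0-9]*\.?[0-9]+([eE][-+]?[0-9]+)?\Z"),
    "Z": re.compile(r"[ !-~]*\Z"),
    "J": re.compile(r"[ !-~]+\Z"),
    "H": re.compile(r"[0-9A-F]+\Z"),
    "B": re.compile(r"[cCsSiIf](,[-+0-9eE.]+)+\Z"),
}

# Tags with a datatype fixed by the GFA specification or by the custom
# tracking fields this package writes (or: origin, mp: merged positions,
# rn: inversion coordinates, cn: copy number).
PREDEFINED_TAG_TYPES = {
    "VN": "Z",
    "LN": "i",
    "RC": "i",
    "KC": "i",
    "FC": "i",
    "cn": "i",
    "or": "Z",
    "mp": "B",
    "rn": "B",
}

_B_INT_SUBTYPES = set("cCsSiI")


def _float_str(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    s = repr(float(x))
    return s


@dataclass
class Tag:
    """One optional field: two-character name, datatype code, native value.

    For B arrays the element subtype code is kept in :attr:`subtype`.
    """

    name: str
    datatype: str
    value: Any
    subtype: str | None = None  # B arrays only

    def __post_init__(self) -> None:
        if not TAG_NAME_RE.match(self.name):
            raise InvalidTagName(f"invalid tag name {self.name!r}")
        if self.datatype not in TAG_VALUE_RE:
            raise MalformedTag(f"unknown tag datatype {self.datatype!r}")
        if self.datatype == "B" and self.subtype is None:
            self.subtype = "f" if any(isinstance(v, float) for v in self.value) else "i"

    # -- text conversion ----------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "Tag":
        parts = text.split(":", 2)
        if len(parts) != 3:
            raise MalformedTag(f"tag field {text!r} is not name:type:value")
        name, datatype, raw = parts
        if not TAG_NAME_RE.match(name):
            raise MalformedTag(f"invalid tag name {name!r}")
        if datatype not in TAG_VALUE_RE:
            raise MalformedTag(f"unknown tag datatype {datatype!r} in {text!r}")
        try:
            if datatype == "i":
                return cls(name, "i", int(raw))
            if datatype == "f":
                return cls(name, "f", float(raw))
            if datatype == "J":
                return cls(name, "J", json.loads(raw))
            if datatype == "B":
                sub, *items = raw.split(",")
                if sub not in "cCsSiIf" or not items:
                    raise MalformedTag(f"malformed B array {raw!r}")
                conv = int if sub in _B_INT_SUBTYPES else float
                return cls(name, "B", [conv(i) for i in items], subtype=sub)
        except (ValueError, json.JSONDecodeError) as exc:
            raise MalformedTag(f"bad {datatype} value in tag {text!r}: {exc}") from exc
        if datatype in ("A", "Z", "H") and not TAG_VALUE_RE[datatype].match(raw):
            raise MalformedTag(f"bad {datatype} value in tag {text!r}")
        return cls(name, datatype, raw)

    def render_value(self) -> str:
        if self.datatype == "i":
            return str(self.value)
        if self.datatype == "f":
            return _float_str(self.value)
        if self.datatype == "J":
            return json.dumps(self.value, separators=(",", ":"), sort_keys=True)
        if self.datatype == "B":
            return ",".join([self.subtype] + [
                str(v) if self.subtype in _B_INT_SUBTYPES else _float_str(v)
                for v in self.value
            ])
        return str(self.value)

    def render(self) -> str:
        return f"{self.name}:{self.datatype}:{self.render_value()}"

    # -- comparison ---------------------------------------------------

    def _key(self) -> tuple:
        v = self.value
        if self.datatype == "J":
            v = json.dumps(v, sort_keys=True, separators=(",", ":"))
        elif self.datatype == "B":
            v = (self.subtype, tuple(v))
        return (self.name, self.datatype, v)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Tag) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


def _infer_datatype(value: Any) -> tuple[str, Any]:
    """Map a native value to (datatype, value) for tag creation."""
    if isinstance(value, bool):
        raise TypeMismatch("boolean has no GFA tag datatype")
    if isinstance(value, int):
        return "i", value
    if isinstance(value, float):
        return "f", value
    if isinstance(value, str):
        return "Z", value
    if isinstance(value, (list, tuple)):
        if value and all(isinstance(v, (int, float)) and not isinstance(v, bool)
                         for v in value):
            return "B", list(value)
        return "J", list(value)
    if isinstance(value, dict):
        return "J", value
    raise TypeMismatch(f"cannot infer a tag datatype for {type(value).__name__}")


def _coerce(value: Any, datatype: str) -> Any:
    """Check/convert a native value against a declared datatype."""
    if datatype == "i":
        if isinstance(value, int) and not isinstance(value, bool):
            return value
        raise TypeMismatch(f"datatype i requires an integer, got {value!r}")
    if datatype == "f":
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        raise TypeMismatch(f"datatype f requires a number, got {value!r}")
    if datatype in ("Z", "H", "A"):
        if not isinstance(value, str):
            raise TypeMismatch(f"datatype {datatype} requires a string, got {value!r}")
        if not TAG_VALUE_RE[datatype].match(value):
            raise TypeMismatch(f"value {value!r} does not fit datatype {datatype}")
        return value
    if datatype == "B":
        if (isinstance(value, (list, tuple)) and value
                and all(isinstance(v, (int, float)) and not isinstance(v, bool)
                        for v in value)):
            return list(value)
        raise TypeMismatch(f"datatype B requires a non-empty numeric list, got {value!r}")
    if datatype == "J":
        try:
            json.dumps(value)
        except (TypeError, ValueError) as exc:
            raise TypeMismatch(f"value is not JSON-serializable: {exc}") from exc
        return value
    raise TypeMismatch(f"unknown datatype {datatype!r}")


@dataclass
class GfaRecord:
    """Base class: a record code, positional fields and an ordered tag set."""

    tags: dict[str, Tag] = field(default_factory=dict)

    code: str = ""  # overridden per subclass

    # -- tag access ---------------------------------------------------

    def get_tag(self, name: str, default: Any = None) -> Any:
        if not TAG_NAME_RE.match(name):
            raise InvalidTagName(f"invalid tag name {name!r}")
        tag = self.tags.get(name)
        return default if tag is None else tag.value

    def set_tag(self, name: str, value: Any, datatype: str | None = None) -> "GfaRecord":
        if not TAG_NAME_RE.match(name):
            raise InvalidTagName(f"invalid tag name {name!r}")
        if datatype is None:
            datatype = PREDEFINED_TAG_TYPES.get(name)
        if datatype is None:
            datatype, value = _infer_datatype(value)
        else:
            value = _coerce(value, datatype)
        old = self.tags.get(name)
        sub = old.subtype if old is not None and old.datatype == datatype == "B" else None
        self.tags[name] = Tag(name, datatype, value, subtype=sub)
        return self

    def delete_tag(self, name: str) -> "GfaRecord":
        self.tags.pop(name, None)
        return self

    def has_tag(self, name: str) -> bool:
        return name in self.tags

    # -- rendering ----------------------------------------------------

    def _positional(self) -> list[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def render(self) -> str:
        return "\t".join([self.code] + self._positional()
                         + [t.render() for t in self.tags.values()])

    def __str__(self) -> str:
        return self.render()

    # -- comparison (tag order ignored) -------------------------------

    def _key(self) -> tuple:
        return (self.code, tuple(self._positional()),
                frozenset(t._key() for t in self.tags.values()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GfaRecord) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def copy(self) -> "GfaRecord":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass(eq=False)
class HeaderRecord(GfaRecord):
    code: str = "H"

    def _positional(self) -> list[str]:
        return []


@dataclass(eq=False)
class SegmentRecord(GfaRecord):
    name: str = ""
    sequence: str = "*"
    code: str = "S"

    def _positional(self) -> list[str]:
        return [self.name, self.sequence]

    @property
    def length(self) -> int | None:
        """Sequence length if known: from the sequence, else the LN tag."""
        if self.sequence != "*":
            return len(self.sequence)
        ln = self.get_tag("LN")
        return ln if isinstance(ln, int) else None


@dataclass(eq=False)
class LinkRecord(GfaRecord):
    from_name: str = ""
    from_orient: str = "+"
    to_name: str = ""
    to_orient: str = "+"
    overlap: str = "*"
    code: str = "L"

    def _positional(self) -> list[str]:
        return [self.from_name, self.from_orient,
                self.to_name, self.to_orient, self.overlap]

    def key(self) -> tuple:
        return (self.from_name, self.from_orient,
                self.to_name, self.to_orient, self.overlap)


@dataclass(eq=False)
class ContainmentRecord(GfaRecord):
    from_name: str = ""
    from_orient: str = "+"
    to_name: str = ""
    to_orient: str = "+"
    pos: int = 0
    overlap: str = "*"
    code: str = "C"

    def _positional(self) -> list[str]:
        return [self.from_name, self.from_orient,
                self.to_name, self.to_orient, str(self.pos), self.overlap]

    def key(self) -> tuple:
        return (self.from_name, self.from_orient, self.to_name,
                self.to_orient, self.pos, self.overlap)


@dataclass(eq=False)
class PathRecord(GfaRecord):
    name: str = ""
    segment_names: list[tuple[str, str]] = field(default_factory=list)
    overlaps: list[str] | None = None  # None renders as "*"
    code: str = "P"

    def _positional(self) -> list[str]:
        segs = ",".join(f"{n}{o}" for n, o in self.segment_names)
        ovls = "*" if self.overlaps is None else ",".join(self.overlaps)
        return [self.name, segs, ovls]


@dataclass(eq=False)
class OpaqueRecord(GfaRecord):
    """Verbatim storage of an unparseable line (lenient mode only)."""

    text: str = ""
    code: str = "#"

    def render(self) -> str:
        return self.text

    def _positional(self) -> list[str]:
        return [self.text]


_RECORD_CODES = {"H", "S", "L", "C", "P"}


def _parse_tags(fields: Iterable[str]) -> dict[str, Tag]:
    tags: dict[str, Tag] = {}
    for f_ in fields:
        tag = Tag.parse(f_)
        if tag.name in tags:
            raise MalformedTag(f"duplicate tag {tag.name!r} on one line")
        tags[tag.name] = tag
    return tags


def _require(fields: list[str], n: int, code: str) -> None:
    if len(fields) < n + 1:
        raise MissingRequiredField(
            f"record type {code} requires {n} fields, got {len(fields) - 1}")


def parse_record(line: str) -> GfaRecord:
    """Parse one tab-separated GFA1 line into a typed record.

    Raises :class:`UnknownRecordType`, :class:`MissingRequiredField` or
    :class:`MalformedTag` on malformed input.
    """
    line = line.rstrip("\n")
    if not line:
        raise MissingRequiredField("empty line")
    fields = line.split("\t")
    code = fields[0]
    if code not in _RECORD_CODES:
        raise UnknownRecordType(f"unknown record type {code!r}")
    if code == "H":
        return HeaderRecord(tags=_parse_tags(fields[1:]))
    if code == "S":
        _require(fields, 2, code)
        return SegmentRecord(name=fields[1], sequence=fields[2],
                             tags=_parse_tags(fields[3:]))
    if code == "L":
        _require(fields, 5, code)
        return LinkRecord(from_name=fields[1], from_orient=fields[2],
                          to_name=fields[3], to_orient=fields[4],
                          overlap=fields[5], tags=_parse_tags(fields[6:]))
    if code == "C":
        _require(fields, 6, code)
        try:
            pos = int(fields[5])
        except ValueError as exc:
            raise MissingRequiredField(f"containment pos {fields[5]!r} not an integer") from exc
        return ContainmentRecord(from_name=fields[1], from_orient=fields[2],
                                 to_name=fields[3], to_orient=fields[4],
                                 pos=pos, overlap=fields[6],
                                 tags=_parse_tags(fields[7:]))
    # P
    _require(fields, 3, code)
    seg_field = fields[2]
    segment_names: list[tuple[str, str]] = []
    for item in seg_field.split(","):
        if len(item) < 2 or item[-1] not in "+-":
            raise MissingRequiredField(f"bad oriented segment {item!r} in path")
        segment_names.append((item[:-1], item[-1]))
    overlaps = None if fields[3] == "*" else fields[3].split(",")
    return PathRecord(name=fields[1], segment_names=segment_names,
                      overlaps=overlaps, tags=_parse_tags(fields[4:]))


def render_record(rec: GfaRecord) -> str:
    """Canonical tab-separated text of a record (tags in insertion order)."""
    return rec.render()


# ---------------------------------------------------------------------------
# validation


def validate_line(line: str) -> list[str]:
    """Violations for one line of GFA text; parse failures count as one."""
    try:
        rec = parse_record(line)
    except (UnknownRecordType, MissingRequiredField, MalformedTag) as exc:
        return [str(exc)]
    return validate_record(rec)


def _check(cond: bool, msg: str, out: list[str]) -> None:
    if not cond:
        out.append(msg)


def validate_record(rec: GfaRecord) -> list[str]:
    """Return a list of format violations; an empty list means valid.

    Checks positional fields and tag names/values against the GFA1
    regular expressions; nothing is raised.
    """
    v: list[str] = []
    if isinstance(rec, OpaqueRecord):
        return [f"unparseable line stored verbatim: {rec.text!r}"]
    if isinstance(rec, SegmentRecord):
        _check(bool(SEGMENT_NAME_RE.match(rec.name)),
               f"invalid segment name {rec.name!r}", v)
        _check(bool(SEQUENCE_RE.match(rec.sequence)),
               f"invalid sequence for segment {rec.name!r}", v)
        ln = rec.get_tag("LN")
        if isinstance(ln, int) and rec.sequence != "*":
            _check(ln == len(rec.sequence),
                   f"LN tag {ln} != sequence length {len(rec.sequence)} "
                   f"on segment {rec.name!r}", v)
    elif isinstance(rec, LinkRecord):
        for nm in (rec.from_name, rec.to_name):
            _check(bool(SEGMENT_NAME_RE.match(nm)), f"invalid name {nm!r} in link", v)
        for o in (rec.from_orient, rec.to_orient):
            _check(bool(ORIENT_RE.match(o)), f"invalid orientation {o!r} in link", v)
        _check(bool(OVERLAP_RE.match(rec.overlap)),
               f"invalid overlap {rec.overlap!r} in link", v)
    elif isinstance(rec, ContainmentRecord):
        for nm in (rec.from_name, rec.to_name):
            _check(bool(SEGMENT_NAME_RE.match(nm)),
                   f"invalid name {nm!r} in containment", v)
        for o in (rec.from_orient, rec.to_orient):
            _check(bool(ORIENT_RE.match(o)),
                   f"invalid orientation {o!r} in containment", v)
        _check(rec.pos >= 0, f"negative containment pos {rec.pos}", v)
        _check(bool(OVERLAP_RE.match(rec.overlap)),
               f"invalid overlap {rec.overlap!r} in containment", v)
    elif isinstance(rec, PathRecord):
        _check(bool(SEGMENT_NAME_RE.match(rec.name)),
               f"invalid path name {rec.name!r}", v)
        _check(len(rec.segment_names) > 0, f"path {rec.name!r} has no segments", v)
        for nm, o in rec.segment_names:
            _check(bool(SEGMENT_NAME_RE.match(nm)),
                   f"invalid name {nm!r} in path {rec.name!r}", v)
            _check(o in "+-", f"invalid orientation {o!r} in path {rec.name!r}", v)
        if rec.overlaps is not None:
            _check(len(rec.overlaps) == max(len(rec.segment_names) - 1, 0),
                   f"path {rec.name!r}: {len(rec.overlaps)} overlaps for "
                   f"{len(rec.segment_names)} segments", v)
            for ov in rec.overlaps:
                _check(bool(OVERLAP_RE.match(ov)),
                       f"invalid overlap {ov!r} in path {rec.name!r}", v)
    for tag in rec.tags.values():
        _check(bool(TAG_NAME_RE.match(tag.name)), f"invalid tag name {tag.name!r}", v)
        _check(bool(TAG_VALUE_RE[tag.datatype].match(tag.render_value())),
               f"tag {tag.name!r} value does not match datatype "
               f"{tag.datatype}: {tag.render_value()!r}", v)
        pre = PREDEFINED_TAG_TYPES.get(tag.name)
        if pre is not None and tag.name.isupper():
            _check(tag.datatype == pre,
                   f"predefined tag {tag.name} must have datatype {pre}", v)
    return v
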