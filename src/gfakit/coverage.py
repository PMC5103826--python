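"""Coverage from count tags and piecewise copy-number estimation.

GFA segments may carry a supporting count *c* in one of three predefined
integer tags: RC (reads), KC (k-mers) or FC (fragments).  Given the unit
length l (average read/fragment length, or k for k-mer counts), the
coverage of a segment s is

    coverage(c, s, l) = c / (|s| - l + 1)

i.e. the count divided by the number of placement positions, which
corrects the underestimate on short segments.  With the degenerate
default l = 1 this reduces to c / |s|.

The copy number of a segment with coverage cov is estimated from a
user-supplied single-copy coverage scov (and a minimal coverage mincov,
by default 0.25 * scov) as

    cn = 0                      if cov < mincov
    cn = 1                      if mincov <= cov < 1.5 * scov
    cn = floor(cov/scov + 0.5)  otherwise

The upper bound of the cn = 1 band is strict: cov = 1.5 * scov rounds to 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import MissingCountTag, NonPositiveDenominator
from .records import SegmentRecord

__all__ = ["CoverageParams", "CopyNumberParams", "segment_coverage",
           "copy_number", "tag_copy_numbers"]

COUNT_TAGS = ("RC", "KC", "FC")


@dataclass(frozen=True)
class CoverageParams:
    """Which count tag to use and the unit length l in bases."""

    count_tag: str = "RC"
    unit_length: int = 1

    def __post_init__(self) -> None:
        if self.count_tag not in COUNT_TAGS:
            raise ValueError(f"count_tag must be one of {COUNT_TAGS}")
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")


@dataclass(frozen=True)
class CopyNumberParams:
    """Single-copy coverage scov and minimal coverage mincov (default scov/4)."""

    scov: float
    mincov: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scov <= 0:
            raise ValueError("scov must be positive")
        if self.mincov is None:
            object.__setattr__(self, "mincov", 0.25 * self.scov)
        if not 0 <= self.mincov < self.scov:
            raise ValueError("mincov must satisfy 0 <= mincov < scov")


def segment_coverage(segment: SegmentRecord, params: CoverageParams) -> float:
    """c / (|s| - l + 1) for the configured count tag."""
    c = segment.get_tag(params.count_tag)
    if c is None:
        raise MissingCountTag(
            f"segment {segment.name!r} lacks the {params.count_tag} tag")
    length = segment.length
    if length is None:
        raise MissingCountTag(f"segment {segment.name!r} has unknown length")
    denom = length - params.unit_length + 1
    if denom < 1:
        raise NonPositiveDenominator(
            f"segment {segment.name!r}: |s|={length} < unit length "
            f"{params.unit_length}")
    return c / denom


def copy_number(cov: float, params: CopyNumberParams) -> int:
    """Piecewise copy-number estimate (see module docstring)."""
    if cov < params.mincov:
        return 0
    if cov < 1.5 * params.scov:
        return 1
    return math.floor(cov / params.scov + 0.5)


def tag_copy_numbers(graph, coverage_params: CoverageParams,
                     cn_params: CopyNumberParams):
    """Set (or overwrite) the custom ``cn:i`` tag on every segment."""
    for seg in graph.segments.values():
        cov = segment_coverage(seg, coverage_params)
        seg.set_tag("cn", copy_number(cov, cn_params))
    return graph
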