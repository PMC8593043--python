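"""Split layer geometry against a slice layout.

Every rendered fragment must lie wholly inside one visible slice, so
segments are cut with exact linear interpolation at slice boundaries,
bars are intersected with each slice along the value axis, and point-like
geometry (markers, text anchors, reference lines) is routed to the slice
containing its broken-axis coordinate.  Anything strictly inside a gap is
discarded — annotation is dropped with a warning rather than relocated,
because silently moving an annotation falsifies it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .break_model import BreakWarning, Interval, InvalidDatumError
from .layout import SliceLayout

__all__ = [
    "Segment",
    "BarFragment",
    "ReferenceLine",
    "clip_segment_to_slices",
    "clip_bar",
    "assign_point_layers",
    "replicate_reference_lines",
]

_EPS_T = 1e-12  # parameter-space tolerance below which a fragment is a point


@dataclass(frozen=True)
class Segment:
    """A straight segment between two points in data units."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1):
            if not (math.isfinite(p[0]) and math.isfinite(p[1])):
                raise InvalidDatumError(f"segment endpoint {p} must be finite")

    def lerp(self, t: float) -> tuple[float, float]:
        return (
            self.p0[0] + t * (self.p1[0] - self.p0[0]),
            self.p0[1] + t * (self.p1[1] - self.p0[1]),
        )


@dataclass(frozen=True)
class BarFragment:
    """The part of one bar falling inside one slice of the value axis."""

    category_position: float
    value_interval: Interval
    slice_index: int


@dataclass(frozen=True)
class ReferenceLine:
    """An axis-parallel reference line (hline: constant y, vline: constant x)."""

    kind: Literal["hline", "vline"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("hline", "vline"):
            raise InvalidDatumError(f"kind must be 'hline' or 'vline', got {self.kind!r}")
        if not math.isfinite(self.value):
            raise InvalidDatumError(f"reference line value must be finite, got {self.value}")


def _axis_coord(p: tuple[float, float], axis: str) -> float:
    return p[0] if axis == "x" else p[1]


def _clamp_axis(p: tuple[float, float], data: Interval, axis: str) -> tuple[float, float]:
    if axis == "x":
        return (min(max(p[0], data.lo), data.hi), p[1])
    return (p[0], min(max(p[1], data.lo), data.hi))


def clip_segment_to_slices(seg: Segment, layout: SliceLayout) -> list[Segment]:
    """Cut a segment into sub-segments, one per slice it intersects.

    Endpoints are linearly interpolated exactly at slice boundaries;
    portions inside gaps are discarded; fragment order follows the original
    direction of travel; degenerate zero-length fragments are dropped.
    """
    a0 = _axis_coord(seg.p0, layout.axis)
    a1 = _axis_coord(seg.p1, layout.axis)
    if a0 == a1:
        # perpendicular to the broken axis: wholly in or wholly out
        return [seg] if layout.slice_index_of(a0) is not None else []
    d = a1 - a0
    pieces: list[tuple[float, Segment]] = []
    for s in layout.slices:
        t_a = (s.data.lo - a0) / d
        t_b = (s.data.hi - a0) / d
        t0, t1 = (t_a, t_b) if t_a <= t_b else (t_b, t_a)
        t0 = max(t0, 0.0)
        t1 = min(t1, 1.0)
        if t1 - t0 > _EPS_T:
            p0, p1 = seg.lerp(t0), seg.lerp(t1)
            # clamp float noise so endpoints sit exactly on slice boundaries,
            # never a ulp inside the open gap
            p0 = _clamp_axis(p0, s.data, layout.axis)
            p1 = _clamp_axis(p1, s.data, layout.axis)
            pieces.append((t0, Segment(p0, p1)))
    pieces.sort(key=lambda p: p[0])
    return [frag for _, frag in pieces]


def clip_bar(
    category_position: float,
    value: float,
    baseline: float,
    layout: SliceLayout,
) -> list[BarFragment]:
    """Intersect a bar's value extent with every visible slice.

    The bar covers ``[min(baseline, value), max(baseline, value)]`` on the
    broken (value) axis; each nonempty intersection with a slice becomes a
    fragment tagged with that slice.  A bar spanning a gap therefore shows
    up in multiple panels with a visual break between — bars are clipped,
    never rescaled.
    """
    for v in (category_position, value, baseline):
        if not math.isfinite(v):
            raise InvalidDatumError(f"bar coordinate must be finite, got {v}")
    lo, hi = min(baseline, value), max(baseline, value)
    if lo == hi:
        return []
    extent = Interval(lo, hi)
    out: list[BarFragment] = []
    for i, s in enumerate(layout.slices):
        inter = extent.intersect(s.data)
        if inter is not None:
            out.append(BarFragment(category_position, inter, i))
    return out


def assign_point_layers(
    points: Sequence[tuple],
    layout: SliceLayout,
) -> tuple[list[list[tuple]], int]:
    """Route ``(x, y, payload...)`` points to the slice containing each one.

    Returns per-slice lists (in slice order) and the number of points
    dropped because they fell inside a gap or outside the data range; a
    summary warning reports the dropped count.  A point exactly on a gap
    boundary belongs to the adjoining visible slice (closed-slice rule).
    """
    per_slice: list[list[tuple]] = [[] for _ in layout.slices]
    dropped = 0
    for pt in points:
        coord = pt[0] if layout.axis == "x" else pt[1]
        if not math.isfinite(coord):
            raise InvalidDatumError(f"point coordinate must be finite, got {coord}")
        i = layout.slice_index_of(coord)
        if i is None:
            dropped += 1
        else:
            per_slice[i].append(pt)
    if dropped:
        warnings.warn(
            f"{dropped} point(s) fell inside a removed range or outside the "
            "axis range and were dropped",
            BreakWarning,
            stacklevel=2,
        )
    return per_slice, dropped


def replicate_reference_lines(
    line: ReferenceLine, layout: SliceLayout
) -> list[tuple[int, ReferenceLine]]:
    """Place a reference line into the panels it belongs to.

    A line perpendicular to the broken axis (its constant coordinate lives
    on the *other* axis) crosses every panel and is replicated into each.
    A line parallel to the broken axis appears only in the slice containing
    its coordinate; inside a gap it is dropped with a warning.
    """
    constant_axis = "y" if line.kind == "hline" else "x"
    if constant_axis != layout.axis:
        return [(i, line) for i in range(layout.n)]
    i = layout.slice_index_of(line.value)
    if i is None:
        warnings.warn(
            f"{line.kind} at {line.value} falls inside a removed range; dropped",
            BreakWarning,
            stacklevel=2,
        )
        return []
    return [(i, line)]
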