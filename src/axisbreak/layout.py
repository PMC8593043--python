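"""Resolve axis transforms into slice layouts and canvas coordinates.

A :class:`SliceLayout` is the fully resolved form of a break/cut/wrap
declaration: an ordered list of visible data slices, each owning a *band*
of the normalised canvas axis [0, 1], separated by fixed blank spacing.
``data_to_canvas`` / ``canvas_to_data`` give the bidirectional
piecewise-linear transform every downstream consumer (clipping, ticks,
rendering) relies on.

The canvas runs 0 → 1 left-to-right for x and bottom-to-top for y; slices
are always stored in increasing data order.  Wrap mode is the exception to
the shared-canvas picture: each row maps its own sub-range onto the full
[0, 1] width, so wrap bands all read (0, 1) and the conservation law does
not apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

from .break_model import (
    AxisBreakSpec,
    AxisCutSpec,
    AxisBreakError,
    DEFAULT_EXPAND_FRACTION,
    Interval,
    InvalidDatumError,
    LayoutInfeasibleError,
    WrapSpec,
    normalize_gaps,
    validate_cuts,
)

__all__ = [
    "IN_GAP",
    "OUT_OF_RANGE",
    "BETWEEN_PANELS",
    "Slice",
    "SliceLayout",
    "partition",
    "allocate_bands",
    "cut_layout",
    "wrap_partition",
    "wrap_layout",
    "identity_layout",
    "expand_outer_slices",
    "resolve_layout",
    "data_to_canvas",
    "canvas_to_data",
]

LayoutMode = Literal["break", "cut", "wrap", "identity"]


class _Sentinel:
    """Singleton marker returned instead of a coordinate."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return f"<{self.name}>"


#: datum falls strictly inside a removed range
IN_GAP = _Sentinel("in-gap")
#: datum falls outside the total data range of the layout
OUT_OF_RANGE = _Sentinel("out-of-range")
#: canvas coordinate falls in the blank spacing between panels
BETWEEN_PANELS = _Sentinel("between-panels")


@dataclass(frozen=True)
class Slice:
    """One visible slice: its data interval, canvas band, and zoom factor.

    ``zoom`` is canvas extent per data unit — the quantity that makes
    "zoom in / zoom out" precise: a slice with a larger zoom factor is
    magnified relative to one with a smaller factor.
    """

    data: Interval
    band: Interval
    zoom: float

    @classmethod
    def make(cls, data: Interval, band: Interval) -> "Slice":
        if band.lo < -1e-12 or band.hi > 1 + 1e-12:
            raise AxisBreakError(f"band ({band.lo}, {band.hi}) must lie within [0, 1]")
        return cls(data=data, band=band, zoom=band.span / data.span)


@dataclass(frozen=True)
class SliceLayout:
    """The resolved layout of a transformed axis."""

    axis: Literal["x", "y"]
    slices: tuple[Slice, ...]
    space: float
    mode: LayoutMode

    @property
    def n(self) -> int:
        return len(self.slices)

    @property
    def total_range(self) -> Interval:
        return Interval(self.slices[0].data.lo, self.slices[-1].data.hi)

    def slice_index_of(self, x: float) -> Optional[int]:
        """Index of the first (lowest) slice whose closed data interval
        contains ``x``, or None.  At a shared cut boundary the lower slice
        wins, matching the tick-dedupe convention."""
        for i, s in enumerate(self.slices):
            if s.data.contains(x):
                return i
        return None

    def gaps(self) -> list[Interval]:
        """Open intervals between consecutive slice data ranges (empty in
        cut/wrap/identity modes where slices are contiguous)."""
        out = []
        for a, b in zip(self.slices, self.slices[1:]):
            if b.data.lo > a.data.hi:
                out.append(Interval(a.data.hi, b.data.lo))
        return out


def partition(axis_range: Interval, gaps: Sequence[Interval]) -> list[Interval]:
    """Complement of the (normalized) gaps: the closed visible slices.

    Their union plus the open gaps tiles ``axis_range``; always returns
    ``len(gaps) + 1`` intervals in increasing order.
    """
    edges = [axis_range.lo]
    for g in gaps:
        edges.extend((g.lo, g.hi))
    edges.append(axis_range.hi)
    return [Interval(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]


def _bands_from_extents(extents: Sequence[float], space: float) -> list[Interval]:
    bands = []
    pos = 0.0
    for i, e in enumerate(extents):
        bands.append(Interval(pos, pos + e))
        pos += e
        if i < len(extents) - 1:
            pos += space
    return bands


def allocate_bands(
    slices: Sequence[Interval],
    scales: Sequence[float],
    space: float,
    axis: Literal["x", "y"] = "x",
    mode: LayoutMode = "break",
) -> SliceLayout:
    """Allot each slice a canvas band weighted by span and zoom scale.

    Slice 1 has weight equal to its data span; slice ``i+1`` has weight
    ``span * scales[i]`` (the scale follows the gap it comes after).  The
    canvas available after spacing, ``1 - space * (n - 1)``, is divided in
    proportion to these weights, so all scales equal to 1 reproduces
    span-proportional layout.
    """
    slices = list(slices)
    n = len(slices)
    if len(scales) != n - 1:
        raise AxisBreakError(f"need {n - 1} scales for {n} slices, got {len(scales)}")
    available = 1.0 - space * (n - 1)
    if available <= 0:
        raise LayoutInfeasibleError(
            f"space {space} with {n} slices leaves no canvas for panels"
        )
    weights = [slices[0].span] + [s.span * k for s, k in zip(slices[1:], scales)]
    total = sum(weights)
    extents = [available * w / total for w in weights]
    bands = _bands_from_extents(extents, space)
    return SliceLayout(
        axis=axis,
        slices=tuple(Slice.make(d, b) for d, b in zip(slices, bands)),
        space=space,
        mode=mode if n > 1 else "identity",
    )


def cut_layout(
    axis_range: Interval,
    cuts: Sequence[float],
    weights: Union[str, Sequence[float]],
    space: float,
    axis: Literal["x", "y"] = "x",
) -> SliceLayout:
    """Contiguous slices between {lo, cuts..., hi} with weight-proportional bands.

    ``"proportional"`` weights reproduce span-proportional bands (no zoom);
    explicit weights allocate band extents in proportion to the weights
    regardless of span, which is exactly how a slice gets magnified.
    """
    cuts = validate_cuts(cuts, axis_range)
    bounds = [axis_range.lo, *cuts, axis_range.hi]
    slices = [Interval(a, b) for a, b in zip(bounds, bounds[1:])]
    n = len(slices)
    if isinstance(weights, str):
        if weights != "proportional":
            raise AxisBreakError(f"unknown weights sentinel {weights!r}")
        w = [s.span for s in slices]
    else:
        w = [float(v) for v in weights]
        if len(w) != n:
            raise AxisBreakError(f"need {n} weights for {n} slices, got {len(w)}")
        if any(v <= 0 for v in w):
            raise AxisBreakError("weights must all be positive")
    available = 1.0 - space * (n - 1)
    if available <= 0:
        raise LayoutInfeasibleError(
            f"space {space} with {n} slices leaves no canvas for panels"
        )
    total = sum(w)
    extents = [available * v / total for v in w]
    bands = _bands_from_extents(extents, space)
    return SliceLayout(
        axis=axis,
        slices=tuple(Slice.make(d, b) for d, b in zip(slices, bands)),
        space=space,
        mode="cut" if n > 1 else "identity",
    )


def wrap_partition(axis_range: Interval, n_rows: int) -> list[Interval]:
    """Split the range into ``n_rows`` equal-width contiguous sub-ranges.

    The first interval (lowest data) is displayed as the top row; the
    returned list is in increasing data order.
    """
    if n_rows < 1:
        raise AxisBreakError(f"n_rows must be >= 1, got {n_rows}")
    lo, hi = axis_range.lo, axis_range.hi
    width = (hi - lo) / n_rows
    # carry exact endpoints: compute bounds by interpolation to avoid drift
    bounds = [lo + (hi - lo) * i / n_rows for i in range(n_rows + 1)]
    bounds[0], bounds[-1] = lo, hi
    return [Interval(a, b) for a, b in zip(bounds, bounds[1:])]


def wrap_layout(
    axis_range: Interval, n_rows: int, axis: Literal["x", "y"] = "x"
) -> SliceLayout:
    """Wrap layout: each row's sub-range maps onto the full [0, 1] width."""
    rows = wrap_partition(axis_range, n_rows)
    slices = tuple(Slice.make(r, Interval(0.0, 1.0)) for r in rows)
    return SliceLayout(axis=axis, slices=slices, space=0.0,
                       mode="wrap" if n_rows > 1 else "identity")


def identity_layout(axis_range: Interval, axis: Literal["x", "y"] = "x") -> SliceLayout:
    """Single slice spanning the whole canvas: plain linear rescaling."""
    return SliceLayout(
        axis=axis,
        slices=(Slice.make(axis_range, Interval(0.0, 1.0)),),
        space=0.0,
        mode="identity",
    )


def expand_outer_slices(
    slices: Sequence[Interval], fraction: float = DEFAULT_EXPAND_FRACTION
) -> list[Interval]:
    """Widen only the outermost slice edges by ``fraction`` of their span.

    Inner break edges stay flush — padding a break edge would reopen the
    very space the gap removed.
    """
    out = list(slices)
    first, last = out[0], out[-1]
    if len(out) == 1:
        pad = fraction * first.span
        return [Interval(first.lo - pad, first.hi + pad)]
    out[0] = Interval(first.lo - fraction * first.span, first.hi)
    out[-1] = Interval(last.lo, last.hi + fraction * last.span)
    return out


TransformSpec = Union[AxisBreakSpec, AxisCutSpec, WrapSpec, None]


def resolve_layout(
    transform: TransformSpec,
    data_range: Interval,
    expand_default: bool = True,
) -> SliceLayout:
    """Turn a user declaration plus the data range into a SliceLayout.

    Expansion (outer-edge padding) is applied to the slice data intervals
    *before* band allocation, so padded area competes for canvas like any
    other data.  ``transform=None`` and an empty-gap break spec both yield
    the identity layout, which renders identically to a plain plot.
    """
    if transform is None:
        rng = expand_outer_slices([data_range])[0] if expand_default else data_range
        return identity_layout(rng, axis="x")

    if isinstance(transform, WrapSpec):
        return wrap_layout(data_range, transform.n_rows, axis="x")

    if isinstance(transform, AxisBreakSpec):
        if not transform.gaps:
            slices = [data_range]
            if transform.expand:
                slices = expand_outer_slices(slices)
            return identity_layout(slices[0], axis=transform.axis)
        gaps = normalize_gaps(transform.gaps, data_range)
        scales = transform.broadcast_scales(len(gaps))
        slices = partition(data_range, gaps)
        if transform.expand:
            slices = expand_outer_slices(slices)
        return allocate_bands(slices, scales, transform.space,
                              axis=transform.axis, mode="break")

    if isinstance(transform, AxisCutSpec):
        cuts = validate_cuts(transform.cuts, data_range)
        bounds = [data_range.lo, *cuts, data_range.hi]
        slices: list[Interval] = [Interval(a, b) for a, b in zip(bounds, bounds[1:])]
        if expand_default:
            slices = expand_outer_slices(slices)
        n = len(slices)
        if isinstance(transform.weights, str):
            w = [s.span for s in slices]
        else:
            w = list(transform.weights)
        available = 1.0 - transform.space * (n - 1)
        if available <= 0:
            raise LayoutInfeasibleError(
                f"space {transform.space} with {n} slices leaves no canvas"
            )
        total = sum(w)
        extents = [available * v / total for v in w]
        bands = _bands_from_extents(extents, transform.space)
        return SliceLayout(
            axis=transform.axis,
            slices=tuple(Slice.make(d, b) for d, b in zip(slices, bands)),
            space=transform.space,
            mode="cut" if n > 1 else "identity",
        )

    raise AxisBreakError(f"unknown transform type {type(transform).__name__}")


def data_to_canvas(x: float, layout: SliceLayout):
    """Map a data coordinate to the canvas axis [0, 1].

    Returns :data:`IN_GAP` for a value strictly inside a removed range and
    :data:`OUT_OF_RANGE` outside the total range.  Values exactly at a gap
    boundary map to the adjoining band edge (slices are closed).  In wrap
    mode the result is the within-row coordinate of the value's row.
    """
    if not math.isfinite(x):
        raise InvalidDatumError(f"data coordinate must be finite, got {x}")
    i = layout.slice_index_of(x)
    if i is not None:
        s = layout.slices[i]
        return s.band.lo + s.zoom * (x - s.data.lo)
    rng = layout.total_range
    if rng.lo <= x <= rng.hi:
        return IN_GAP
    return OUT_OF_RANGE


def canvas_to_data(c: float, layout: SliceLayout):
    """Inverse of :func:`data_to_canvas` on band interiors.

    A coordinate falling in the inter-panel spacing returns
    :data:`BETWEEN_PANELS`; outside [0, 1] raises.
    """
    if not math.isfinite(c):
        raise InvalidDatumError(f"canvas coordinate must be finite, got {c}")
    if c < -1e-12 or c > 1 + 1e-12:
        raise AxisBreakError(f"canvas coordinate {c} outside [0, 1]")
    # tolerate float noise at band edges so round trips of boundary values
    # do not fall into the spacing
    tol = 1e-12
    for s in layout.slices:
        if s.band.lo - tol <= c <= s.band.hi + tol:
            x = s.data.lo + (c - s.band.lo) / s.zoom
            return min(max(x, s.data.lo), s.data.hi)
    return BETWEEN_PANELS
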