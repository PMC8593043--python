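"""Domain types and validation for axis-transform declarations.

An axis transform removes ranges from an axis (a *break*, producing a gap
plot), divides it at interior points into reweighted slices (a *cut*,
producing per-slice zoom), or folds it into several rows (a *wrap*).  This
module holds the user-facing declaration types and normalises them into a
canonical form the layout engine can trust: gaps sorted, merged, strictly
interior; cuts sorted, unique, strictly interior.

Conventions
-----------
Gaps are OPEN intervals ``(lo, hi)`` and visible slices CLOSED ``[a, b]``:
a datum sitting exactly on a break boundary is drawn at the adjoining panel
edge rather than silently vanishing.  A gap touching an axis limit is an
error — a break must leave visible data on both sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

__all__ = [
    "AxisBreakError",
    "InvalidIntervalError",
    "OutOfRangeError",
    "DegenerateBreakError",
    "DuplicateCutError",
    "LayoutInfeasibleError",
    "InvalidDatumError",
    "BreakWarning",
    "Interval",
    "AxisBreakSpec",
    "AxisCutSpec",
    "WrapSpec",
    "normalize_gaps",
    "validate_cuts",
]

Axis = Literal["x", "y"]

#: default canvas fraction left blank between adjacent panels
DEFAULT_SPACE = 0.02
#: multiplicative padding applied to the outer edges of the outermost slices
DEFAULT_EXPAND_FRACTION = 0.05
#: upper bound on the per-gap spacing fraction
MAX_SPACE = 0.2


class AxisBreakError(ValueError):
    """Base class for all validation and layout errors in this package."""


class InvalidIntervalError(AxisBreakError):
    """An interval with lo >= hi (empty or inverted)."""


class OutOfRangeError(AxisBreakError):
    """A gap or cut touching or exceeding the axis range."""


class DegenerateBreakError(AxisBreakError):
    """Merged gaps would cover the whole interior of the axis."""


class DuplicateCutError(AxisBreakError):
    """The same cut point given twice."""


class LayoutInfeasibleError(AxisBreakError):
    """Inter-panel spacing leaves no canvas for the panels themselves."""


class InvalidDatumError(AxisBreakError):
    """A non-finite coordinate fed to a transform or clipper."""


class BreakWarning(UserWarning):
    """Non-fatal normalisation events: merged gaps, dropped annotation."""


@dataclass(frozen=True)
class Interval:
    """A range ``[lo, hi]`` on a data axis, in data units.

    Used both for gaps (interpreted as open) and for visible slices
    (interpreted as closed).  Construction rejects empty and inverted
    intervals, so ``span`` is always positive.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo = float(self.lo)
        hi = float(self.hi)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise InvalidIntervalError(f"interval bounds must be finite, got ({self.lo}, {self.hi})")
        if not lo < hi:
            raise InvalidIntervalError(f"interval requires lo < hi, got ({lo}, {hi})")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def span(self) -> float:
        return self.hi - self.lo

    def contains(self, x: float) -> bool:
        """Closed-interval membership (slice convention)."""
        return self.lo <= x <= self.hi

    def strictly_contains(self, x: float) -> bool:
        """Open-interval membership (gap convention)."""
        return self.lo < x < self.hi

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        """Closed intersection, or None when it is empty or a single point."""
        lo = max(self.lo, other.lo)
        hi = min(self.hi, other.hi)
        if lo < hi:
            return Interval(lo, hi)
        return None


IntervalLike = Union[Interval, Sequence[float]]


def _as_interval(obj: IntervalLike) -> Interval:
    if isinstance(obj, Interval):
        return obj
    lo, hi = obj  # type: ignore[misc]
    return Interval(float(lo), float(hi))


def normalize_gaps(gaps: Sequence[IntervalLike], axis_range: IntervalLike) -> list[Interval]:
    """Canonicalise a set of gap intervals against the data range.

    Gaps are sorted by ``lo``; overlapping or exactly touching gaps are
    merged, one :class:`BreakWarning` per merge.  Every gap must be strictly
    interior to ``axis_range`` — a break needs visible data on both sides.
    The union of the returned (open) gaps equals the union of the inputs,
    up to the isolated boundary points absorbed when touching gaps merge.

    Raises
    ------
    InvalidIntervalError
        for a gap with ``lo >= hi``.
    OutOfRangeError
        for a gap touching or exceeding the axis range.
    DegenerateBreakError
        if the merged gaps would cover the whole interior.
    """
    rng = _as_interval(axis_range)
    if not gaps:
        raise AxisBreakError("normalize_gaps requires at least one gap")
    parsed = [_as_interval(g) for g in gaps]
    for g in parsed:
        if g.lo <= rng.lo or g.hi >= rng.hi:
            raise OutOfRangeError(
                f"gap ({g.lo}, {g.hi}) must be strictly inside the axis range "
                f"({rng.lo}, {rng.hi}); a break needs visible data on both sides"
            )
    parsed.sort(key=lambda g: (g.lo, g.hi))
    merged: list[Interval] = [parsed[0]]
    for g in parsed[1:]:
        last = merged[-1]
        if g.lo <= last.hi:  # overlap or exact touch
            warnings.warn(
                f"gaps ({last.lo}, {last.hi}) and ({g.lo}, {g.hi}) overlap; merging",
                BreakWarning,
                stacklevel=2,
            )
            merged[-1] = Interval(last.lo, max(last.hi, g.hi))
        else:
            merged.append(g)
    if len(merged) == 1 and merged[0].lo <= rng.lo and merged[0].hi >= rng.hi:
        raise DegenerateBreakError("merged gaps cover the whole axis interior")
    return merged


def validate_cuts(cuts: Sequence[float], axis_range: IntervalLike) -> list[float]:
    """Sort and validate cut points: unique, finite, strictly interior."""
    rng = _as_interval(axis_range)
    if not cuts:
        raise AxisBreakError("validate_cuts requires at least one cut point")
    vals = [float(c) for c in cuts]
    for c in vals:
        if not math.isfinite(c):
            raise InvalidDatumError(f"cut point must be finite, got {c}")
        if c <= rng.lo or c >= rng.hi:
            raise OutOfRangeError(
                f"cut {c} must lie strictly inside the axis range ({rng.lo}, {rng.hi})"
            )
    out = sorted(vals)
    for a, b in zip(out, out[1:]):
        if a == b:
            raise DuplicateCutError(f"duplicate cut point {a}")
    return out


def _validate_axis(axis: str) -> Axis:
    if axis not in ("x", "y"):
        raise AxisBreakError(f"axis must be 'x' or 'y', got {axis!r}")
    return axis  # type: ignore[return-value]


def _validate_space(space: float) -> float:
    space = float(space)
    if not (0.0 <= space <= MAX_SPACE):
        raise AxisBreakError(f"space must lie in [0, {MAX_SPACE}], got {space}")
    return space


@dataclass(frozen=True)
class AxisBreakSpec:
    """Declaration of one or more gaps (missing ranges) on an axis.

    Parameters
    ----------
    axis : {'x', 'y'}
        Which axis to break.
    gaps : sequence of Interval or (lo, hi) pairs
        Open ranges to remove.  They may overlap (merged with a warning)
        but must each lie strictly inside the data range.
    scales : float or sequence of float
        Zoom factor applied to the slice *following* each gap, relative to
        span-proportional layout; a scalar broadcasts to every gap.
        ``1`` keeps the slice's canvas share proportional to its data span.
    ticklabels : optional sequence of (position, label)
        Explicit tick overrides on the broken axis.
    space : float
        Canvas fraction left blank per inter-panel gap, in [0, 0.2].
    expand : bool
        Apply 5% multiplicative padding to the outer axis edges (never at
        inner break edges).
    """

    axis: Axis
    gaps: tuple[Interval, ...]
    scales: Union[float, tuple[float, ...]] = 1.0
    ticklabels: Optional[tuple[tuple[float, str], ...]] = None
    space: float = DEFAULT_SPACE
    expand: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _validate_axis(self.axis))
        object.__setattr__(self, "gaps", tuple(_as_interval(g) for g in self.gaps))
        object.__setattr__(self, "space", _validate_space(self.space))
        if isinstance(self.scales, (int, float)):
            scales: Union[float, tuple[float, ...]] = float(self.scales)
            if scales <= 0:
                raise AxisBreakError(f"scales must be > 0, got {scales}")
        else:
            scales = tuple(float(s) for s in self.scales)
            for s in scales:
                if s <= 0:
                    raise AxisBreakError(f"scales must all be > 0, got {s}")
        object.__setattr__(self, "scales", scales)
        if self.ticklabels is not None:
            object.__setattr__(
                self,
                "ticklabels",
                tuple((float(p), str(lab)) for p, lab in self.ticklabels),
            )

    def broadcast_scales(self, n_gaps: int) -> list[float]:
        """Per-gap scale factors, broadcasting a scalar."""
        if isinstance(self.scales, float):
            return [self.scales] * n_gaps
        if len(self.scales) != n_gaps:
            raise AxisBreakError(
                f"got {len(self.scales)} scales for {n_gaps} gaps; "
                "give one per gap or a single scalar"
            )
        return list(self.scales)


@dataclass(frozen=True)
class AxisCutSpec:
    """Declaration of contiguous axis divisions with per-slice weights.

    ``cuts`` divide the axis into ``len(cuts) + 1`` contiguous slices; no
    data is removed.  ``weights`` assign each slice a canvas share
    proportional to its weight — unequal weights zoom slices in or out.
    The sentinel ``"proportional"`` reproduces span-proportional layout
    (no zoom).
    """

    axis: Axis
    cuts: tuple[float, ...]
    weights: Union[str, tuple[float, ...]] = "proportional"
    space: float = DEFAULT_SPACE

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _validate_axis(self.axis))
        object.__setattr__(self, "cuts", tuple(float(c) for c in self.cuts))
        object.__setattr__(self, "space", _validate_space(self.space))
        if isinstance(self.weights, str):
            if self.weights != "proportional":
                raise AxisBreakError(
                    f"weights must be positive numbers or 'proportional', got {self.weights!r}"
                )
        else:
            w = tuple(float(v) for v in self.weights)
            if len(w) != len(self.cuts) + 1:
                raise AxisBreakError(
                    f"need len(cuts)+1 = {len(self.cuts) + 1} weights, got {len(w)}"
                )
            for v in w:
                if v <= 0:
                    raise AxisBreakError(f"weights must all be > 0, got {v}")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class WrapSpec:
    """Fold a long x-axis into ``n_rows`` stacked rows of equal data width.

    ``n_rows == 1`` is the identity transform.
    """

    n_rows: int

    def __post_init__(self) -> None:
        n = int(self.n_rows)
        if n < 1:
            raise AxisBreakError(f"n_rows must be >= 1, got {self.n_rows}")
        object.__setattr__(self, "n_rows", n)
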