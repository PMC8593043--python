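"""Per-slice axis ticks: nice positions, label overrides, edge dedupe.

Each visible slice gets its own tick set.  Default positions follow the
classical nice-number scheme (steps of 1, 2 or 5 times a power of ten,
chosen from the slice span and a target count), every emitted position lies
inside its slice's closed data interval, and zoomed-out slices are given
proportionally fewer ticks so small panels stay readable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .break_model import BreakWarning, Interval
from .layout import SliceLayout

__all__ = [
    "TickSet",
    "default_ticks",
    "format_tick",
    "slice_target_counts",
    "apply_ticklabels",
    "dedupe_break_edge_ticks",
]

#: baseline tick count for a slice occupying an average share of the canvas
DEFAULT_TARGET = 5
_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class TickSet:
    """Tick positions and labels for one slice."""

    slice_index: int
    ticks: tuple[tuple[float, str], ...]


def _nice_step(raw: float) -> float:
    """Round a raw step to the nearest 'nice' value {1, 2, 5} x 10^k."""
    exp = math.floor(math.log10(raw))
    frac = raw / 10.0**exp
    if frac < 1.5:
        nice = 1.0
    elif frac < 3.0:
        nice = 2.0
    elif frac < 7.0:
        nice = 5.0
    else:
        nice = 10.0
    return nice * 10.0**exp


def _step_down(step: float) -> float:
    """The next smaller nice step: 5 -> 2 -> 1 -> 0.5 -> ..."""
    exp = math.floor(math.log10(step) + 0.5) if step >= 1 else math.floor(math.log10(step) + 1e-9)
    # recover the mantissa robustly
    exp = math.floor(math.log10(step * (1 + 1e-12)))
    m = round(step / 10.0**exp)
    if m == 5:
        return 2.0 * 10.0**exp
    if m == 2:
        return 1.0 * 10.0**exp
    return 5.0 * 10.0 ** (exp - 1)


def _multiples_within(step: float, lo: float, hi: float) -> list[float]:
    span = hi - lo
    tol = _BOUNDARY_TOL * max(span, abs(lo), abs(hi), 1.0)
    i0 = math.ceil((lo - tol) / step)
    i1 = math.floor((hi + tol) / step)
    out = []
    for i in range(i0, i1 + 1):
        t = i * step
        # clamp float noise onto the closed slice
        t = min(max(t, lo), hi)
        out.append(t)
    return out


def default_ticks(slice_interval: Interval, target_count: int = DEFAULT_TARGET) -> list[float]:
    """Nice tick positions covering one slice.

    Uses the classical nice-number step ``nicenum(span / (target - 1))``
    with step-down fallback so at least two ticks always land inside the
    closed slice; the count never exceeds twice the target.
    """
    if target_count < 2:
        raise ValueError(f"target_count must be >= 2, got {target_count}")
    lo, hi = slice_interval.lo, slice_interval.hi
    step = _nice_step((hi - lo) / (target_count - 1))
    ticks = _multiples_within(step, lo, hi)
    while len(ticks) < 2:
        step = _step_down(step)
        ticks = _multiples_within(step, lo, hi)
    return ticks


def format_tick(x: float) -> str:
    """Deterministic shortest label: positional within |exponent| < 5,
    scientific (``1.5e+06`` style) beyond."""
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    if -5 < exp < 5:
        s = repr(float(x))
        if s.endswith(".0"):
            s = s[:-2]
        return s
    mant = x / 10.0**exp
    ms = repr(round(mant, 10))
    if ms.endswith(".0"):
        ms = ms[:-2]
    return f"{ms}e{exp:+d}"


def slice_target_counts(layout: SliceLayout, base: int = DEFAULT_TARGET) -> list[int]:
    """Target tick count per slice, scaled by canvas band extent (min 2).

    A slice occupying an average share of the canvas gets ``base`` ticks;
    zoomed-out (narrow) slices get proportionally fewer, so small panels
    are not crowded with labels.
    """
    n = layout.n
    return [max(2, round(base * s.band.span * n)) for s in layout.slices]


def apply_ticklabels(
    overrides: Optional[Sequence[tuple[float, str]]],
    layout: SliceLayout,
    base_target: int = DEFAULT_TARGET,
) -> list[TickSet]:
    """Build one TickSet per slice, honouring explicit (position, label) overrides.

    Each override position inside some slice replaces that slice's default
    ticks; positions inside gaps or outside the range are dropped with a
    warning listing them.  Slices with no override fall back to
    :func:`default_ticks` with labels from :func:`format_tick`.
    """
    targets = slice_target_counts(layout, base_target)
    per_slice: list[list[tuple[float, str]]] = [[] for _ in layout.slices]
    dropped: list[float] = []
    for pos, label in overrides or ():
        i = layout.slice_index_of(float(pos))
        if i is None:
            dropped.append(float(pos))
        else:
            per_slice[i].append((float(pos), str(label)))
    if dropped:
        warnings.warn(
            f"ticklabel positions {dropped} fall inside a removed range or "
            "outside the axis range; dropped",
            BreakWarning,
            stacklevel=2,
        )
    out: list[TickSet] = []
    for i, s in enumerate(layout.slices):
        if per_slice[i]:
            ticks = tuple(sorted(per_slice[i]))
        else:
            ticks = tuple((t, format_tick(t)) for t in default_ticks(s.data, targets[i]))
        out.append(TickSet(slice_index=i, ticks=ticks))
    return out


def dedupe_break_edge_ticks(
    ticksets: Sequence[TickSet], layout: SliceLayout
) -> list[TickSet]:
    """Keep a shared-boundary tick only in the lower slice (cut mode).

    In cut (and wrap) mode adjacent slices meet at the same data value, so
    a tick sitting exactly on the boundary would be drawn twice; it is kept
    in the lower slice only (transferred there if absent).  In break mode
    the two edge ticks label distinct data values and both are kept.
    """
    if layout.mode not in ("cut", "wrap"):
        return list(ticksets)
    sets = [list(ts.ticks) for ts in ticksets]
    for i in range(layout.n - 1):
        boundary = layout.slices[i].data.hi
        upper = sets[i + 1]
        hit = [t for t in upper if abs(t[0] - boundary) <= _BOUNDARY_TOL * max(1.0, abs(boundary))]
        if not hit:
            continue
        sets[i + 1] = [t for t in upper if t not in hit]
        lower_positions = {t[0] for t in sets[i]}
        if boundary not in lower_positions:
            sets[i] = sorted(sets[i] + [hit[0]])
    return [
        TickSet(slice_index=i, ticks=tuple(s)) for i, s in enumerate(sets)
    ]
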