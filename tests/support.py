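"""Shared randomized-input builders and independent oracles for the tests.

The oracles here deliberately re-derive expected results by brute force
(dense grids, interval arithmetic, a fresh nice-number implementation)
rather than calling the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from axisbreak import (
    AxisBreakSpec,
    AxisCutSpec,
    Interval,
    SliceLayout,
    WrapSpec,
    allocate_bands,
    partition,
)


def random_range(rng: np.random.Generator) -> Interval:
    lo = float(rng.uniform(-100, 100))
    span = float(rng.uniform(1, 200))
    return Interval(lo, lo + span)


def random_gaps(rng: np.random.Generator, axis_range: Interval, max_gaps: int = 3):
    """Disjoint, strictly interior gaps with comfortable separation."""
    n = int(rng.integers(1, max_gaps + 1))
    # 2n interior breakpoints with minimum relative separation 0.02
    while True:
        pts = np.sort(rng.uniform(0.02, 0.98, size=2 * n))
        if np.all(np.diff(pts) > 0.02):
            break
    lo, span = axis_range.lo, axis_range.span
    return [Interval(lo + pts[2 * i] * span, lo + pts[2 * i + 1] * span) for i in range(n)]


def random_break_layout(rng: np.random.Generator, max_gaps: int = 3) -> SliceLayout:
    axis_range = random_range(rng)
    gaps = random_gaps(rng, axis_range, max_gaps)
    slices = partition(axis_range, gaps)
    scales = [float(rng.uniform(0.2, 5.0)) for _ in gaps]
    space = float(rng.uniform(0, 0.05))
    axis = "x" if rng.random() < 0.5 else "y"
    return allocate_bands(slices, scales, space, axis=axis, mode="break")


def random_break_spec(rng: np.random.Generator, axis_range: Interval) -> AxisBreakSpec:
    gaps = random_gaps(rng, axis_range)
    return AxisBreakSpec(
        axis="x" if rng.random() < 0.5 else "y",
        gaps=tuple((g.lo, g.hi) for g in gaps),
        scales=float(rng.uniform(0.2, 5.0)),
        space=float(rng.uniform(0, 0.05)),
    )


def random_cut_spec(rng: np.random.Generator, axis_range: Interval) -> AxisCutSpec:
    n = int(rng.integers(1, 4))
    while True:
        pts = np.sort(rng.uniform(0.05, 0.95, size=n))
        if n == 1 or np.all(np.diff(pts) > 0.02):
            break
    cuts = tuple(float(axis_range.lo + p * axis_range.span) for p in pts)
    if rng.random() < 0.5:
        weights = "proportional"
    else:
        weights = tuple(float(w) for w in rng.uniform(0.2, 5.0, size=n + 1))
    return AxisCutSpec(axis="x" if rng.random() < 0.5 else "y",
                       cuts=cuts, weights=weights,
                       space=float(rng.uniform(0, 0.05)))


def random_wrap_spec(rng: np.random.Generator) -> WrapSpec:
    return WrapSpec(n_rows=int(rng.integers(1, 7)))


# ---------------------------------------------------------------------------
# oracles


def grid_union_membership(gaps, axis_range: Interval, step: float = 1e-3) -> np.ndarray:
    """Brute-force open-union membership of a regular grid over the range."""
    xs = np.arange(axis_range.lo, axis_range.hi, step)
    member = np.zeros(xs.shape, dtype=bool)
    for g in gaps:
        member |= (xs > g.lo) & (xs < g.hi)
    return member


def anchor_interp_transform(layout: SliceLayout, xs: np.ndarray) -> np.ndarray:
    """Explicit linear interpolation over (slice boundary -> band boundary)
    anchor pairs; valid only at visible (in-slice) positions."""
    xa, ca = [], []
    for s in layout.slices:
        xa.extend([s.data.lo, s.data.hi])
        ca.extend([s.band.lo, s.band.hi])
    return np.interp(xs, xa, ca)


def visible_mask(layout: SliceLayout, xs: np.ndarray) -> np.ndarray:
    mask = np.zeros(xs.shape, dtype=bool)
    for s in layout.slices:
        mask |= (xs >= s.data.lo) & (xs <= s.data.hi)
    return mask


def interval_overlap(lo: float, hi: float, intervals) -> float:
    """Total overlap length of [lo, hi] with a set of intervals."""
    total = 0.0
    for iv in intervals:
        a, b = max(lo, iv.lo), min(hi, iv.hi)
        if b > a:
            total += b - a
    return total


def nice_ticks_oracle(lo: float, hi: float, target: int) -> list[float]:
    """Independent nice-number tick generator (written fresh for checking).

    Same contract: step = nice(span / (target - 1)) with {1, 2, 5} x 10^k
    rounding thresholds at 1.5 / 3 / 7, stepped down the 5-2-1 ladder until
    at least two multiples land in the closed interval.
    """
    def nice(v: float) -> float:
        e = math.floor(math.log10(v))
        f = v / 10**e
        for bound, val in ((1.5, 1.0), (3.0, 2.0), (7.0, 5.0)):
            if f < bound:
                return val * 10**e
        return 10.0 * 10**e

    def down(s: float) -> float:
        e = math.floor(math.log10(s * (1 + 1e-12)))
        m = round(s / 10**e)
        return {5: 2 * 10.0**e, 2: 1 * 10.0**e}.get(m, 5 * 10.0 ** (e - 1))

    def multiples(s: float) -> list[float]:
        tol = 1e-9 * max(hi - lo, abs(lo), abs(hi), 1.0)
        ks = range(math.ceil((lo - tol) / s), math.floor((hi + tol) / s) + 1)
        return [min(max(k * s, lo), hi) for k in ks]

    step = nice((hi - lo) / (target - 1))
    ticks = multiples(step)
    while len(ticks) < 2:
        step = down(step)
        ticks = multiples(step)
    return ticks
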