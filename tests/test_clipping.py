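"""Geometry clipping against slice layouts."""

import numpy as np
import pytest

from axisbreak import (
    BreakWarning,
    Interval,
    InvalidDatumError,
    ReferenceLine,
    Segment,
    allocate_bands,
    assign_point_layers,
    clip_bar,
    clip_segment_to_slices,
    partition,
    replicate_reference_lines,
)
from support import interval_overlap, random_break_layout

RANGE = Interval(0, 10)


def make_layout(gaps):
    slices = partition(RANGE, [Interval(*g) for g in gaps])
    return allocate_bands(slices, [1.0] * len(gaps), 0.0)


class TestClipSegment:
    def test_segment_split_with_interpolated_endpoints(self):
        lay = make_layout([(2, 4)])
        frags = clip_segment_to_slices(Segment((1, 0), (7, 6)), lay)
        assert len(frags) == 2
        assert frags[0].p0 == (1, 0) and frags[0].p1 == (2, 1)
        assert frags[1].p0 == (4, 3) and frags[1].p1 == (7, 6)

    def test_segment_wholly_inside_gap_removed(self):
        lay = make_layout([(2, 4)])
        assert clip_segment_to_slices(Segment((2.5, 0), (3.5, 1)), lay) == []

    def test_segment_avoiding_gaps_untouched(self):
        lay = make_layout([(2, 4)])
        seg = Segment((5, 0), (9, 1))
        assert clip_segment_to_slices(seg, lay) == [seg]

    def test_reversed_segment_keeps_direction(self):
        lay = make_layout([(2, 4)])
        frags = clip_segment_to_slices(Segment((7, 6), (1, 0)), lay)
        assert frags[0].p0 == (7, 6)  # original direction of travel
        assert frags[-1].p1 == (1, 0)

    def test_perpendicular_segment_in_or_out(self):
        lay = make_layout([(2, 4)])
        vert = Segment((1, 0), (1, 5))
        assert clip_segment_to_slices(vert, lay) == [vert]
        assert clip_segment_to_slices(Segment((3, 0), (3, 5)), lay) == []

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidDatumError):
            Segment((float("nan"), 0), (1, 1))

    def test_dense_sampling_oracle(self, rng):
        """Fragments, densely sampled, reproduce the parent line's visible points."""
        for _ in range(40):
            lay = random_break_layout(rng)
            r = lay.total_range
            x0, x1 = sorted(rng.uniform(r.lo, r.hi, size=2))
            if x1 - x0 < 1e-3 * r.span:
                continue
            y0, y1 = rng.uniform(-5, 5, size=2)
            seg = Segment((x0, y0), (x1, y1)) if lay.axis == "x" else Segment((y0, x0), (y1, x1))
            frags = clip_segment_to_slices(seg, lay)
            for frag in frags:  # no fragment crosses a slice boundary
                a = (frag.p0[0], frag.p1[0]) if lay.axis == "x" else (frag.p0[1], frag.p1[1])
                assert any(
                    s.data.lo - 1e-9 <= min(a) and max(a) <= s.data.hi + 1e-9
                    for s in lay.slices
                )
            ts = np.arange(0.0, 1.0, 1e-3)
            ax0, ax1 = (x0, x1)
            xs = ax0 + ts * (ax1 - ax0)
            vs = y0 + ts * (y1 - y0)
            for s_i, (xx, vv) in enumerate(zip(xs, vs)):
                visible = any(s.data.contains(xx) for s in lay.slices)
                covering = [
                    f for f in frags
                    if min(f.p0[0] if lay.axis == "x" else f.p0[1],
                           f.p1[0] if lay.axis == "x" else f.p1[1]) - 1e-9 <= xx
                    <= max(f.p0[0] if lay.axis == "x" else f.p0[1],
                           f.p1[0] if lay.axis == "x" else f.p1[1]) + 1e-9
                ]
                if visible:
                    assert covering, f"visible point {xx} not covered by any fragment"
                    f = covering[0]
                    fa0 = f.p0[0] if lay.axis == "x" else f.p0[1]
                    fa1 = f.p1[0] if lay.axis == "x" else f.p1[1]
                    fo0 = f.p0[1] if lay.axis == "x" else f.p0[0]
                    fo1 = f.p1[1] if lay.axis == "x" else f.p1[0]
                    t = 0.0 if fa1 == fa0 else (xx - fa0) / (fa1 - fa0)
                    assert abs((fo0 + t * (fo1 - fo0)) - vv) <= 1e-6


class TestClipBar:
    def test_bar_across_one_gap(self):
        lay = make_layout([(2, 4)])
        frags = clip_bar(0.0, 9.0, 0.0, lay)
        assert [(f.value_interval.lo, f.value_interval.hi, f.slice_index) for f in frags] == [
            (0, 2, 0),
            (4, 9, 1),
        ]

    def test_short_bar_single_fragment(self):
        lay = make_layout([(2, 4)])
        frags = clip_bar(0.0, 1.5, 0.0, lay)
        assert [(f.value_interval.lo, f.value_interval.hi) for f in frags] == [(0, 1.5)]

    def test_bar_across_two_gaps(self):
        lay = make_layout([(2, 4), (6, 7)])
        frags = clip_bar(0.0, 9.0, 0.0, lay)
        assert [(f.value_interval.lo, f.value_interval.hi) for f in frags] == [
            (0, 2),
            (4, 6),
            (7, 9),
        ]

    def test_negative_bar_below_baseline(self):
        lay = make_layout([(2, 4)])
        frags = clip_bar(0.0, 0.5, 9.0, lay)  # waterfall-style downward bar
        assert [(f.value_interval.lo, f.value_interval.hi) for f in frags] == [
            (0.5, 2),
            (4, 9),
        ]

    def test_measure_conservation_oracle(self, rng):
        """Total fragment extent equals bar extent minus gap overlap."""
        for _ in range(200):
            lay = random_break_layout(rng)
            r = lay.total_range
            v0, v1 = sorted(rng.uniform(r.lo, r.hi, size=2))
            if v1 - v0 < 1e-9:
                continue
            frags = clip_bar(0.0, v1, v0, lay)
            total = sum(f.value_interval.span for f in frags)
            expected = (v1 - v0) - interval_overlap(v0, v1, lay.gaps())
            assert abs(total - expected) <= 1e-9 * max(1.0, r.span)
            for f in frags:  # fragment lies wholly inside its slice
                s = lay.slices[f.slice_index].data
                assert s.lo - 1e-12 <= f.value_interval.lo
                assert f.value_interval.hi <= s.hi + 1e-12


class TestAssignPoints:
    def test_routing_and_gap_drop(self):
        lay = make_layout([(2, 4)])
        per_slice, dropped = assign_point_layers([(1, 0.0), (7, 0.0)], lay)
        assert [len(g) for g in per_slice] == [1, 1]
        assert dropped == 0

    def test_point_in_gap_dropped_with_warning(self):
        lay = make_layout([(2, 4)])
        with pytest.warns(BreakWarning):
            _, dropped = assign_point_layers([(3, 0.0)], lay)
        assert dropped == 1

    def test_boundary_point_belongs_to_adjacent_slice(self):
        lay = make_layout([(2, 4)])
        per_slice, dropped = assign_point_layers([(2, 0.0)], lay)
        assert len(per_slice[0]) == 1 and dropped == 0


class TestReferenceLines:
    def test_perpendicular_line_in_every_panel(self):
        lay = make_layout([(2, 4)])
        placed = replicate_reference_lines(ReferenceLine("hline", 5.0), lay)
        assert [i for i, _ in placed] == [0, 1]

    def test_parallel_line_in_gap_dropped(self):
        lay = make_layout([(2, 4)])
        with pytest.warns(BreakWarning):
            assert replicate_reference_lines(ReferenceLine("vline", 3.0), lay) == []

    def test_parallel_line_routed_to_its_slice(self):
        lay = make_layout([(2, 4)])
        placed = replicate_reference_lines(ReferenceLine("vline", 7.0), lay)
        assert [i for i, _ in placed] == [1]
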