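"""Slice layout resolution and the piecewise-linear canvas transform."""

import numpy as np
import pytest

from axisbreak import (
    BETWEEN_PANELS,
    IN_GAP,
    Interval,
    InvalidDatumError,
    LayoutInfeasibleError,
    OUT_OF_RANGE,
    allocate_bands,
    canvas_to_data,
    cut_layout,
    data_to_canvas,
    partition,
    wrap_layout,
    wrap_partition,
)
from support import (
    anchor_interp_transform,
    random_break_layout,
    visible_mask,
)

RANGE = Interval(0, 10)


def approx_list(xs, ys, tol=1e-12):
    assert len(xs) == len(ys)
    for a, b in zip(xs, ys):
        assert a == pytest.approx(b, abs=tol)


class TestPartition:
    @pytest.mark.parametrize(
        "gaps,expected",
        [
            ([(2, 4)], [(0, 2), (4, 10)]),
            ([(2, 4), (6, 7)], [(0, 2), (4, 6), (7, 10)]),
            ([], [(0, 10)]),
        ],
    )
    def test_complement(self, gaps, expected):
        out = partition(RANGE, [Interval(*g) for g in gaps])
        assert out == [Interval(*e) for e in expected]
        assert len(out) == len(gaps) + 1


class TestAllocateBands:
    def test_equal_scales_are_span_proportional(self):
        lay = allocate_bands([Interval(0, 2), Interval(4, 10)], [1.0], 0.0)
        approx_list([s.band.span for s in lay.slices], [0.25, 0.75])
        approx_list([s.band.lo for s in lay.slices], [0.0, 0.25])
        approx_list([s.band.hi for s in lay.slices], [0.25, 1.0])

    def test_scale_reweights_following_slice(self):
        lay = allocate_bands([Interval(0, 2), Interval(4, 10)], [0.5], 0.0)
        approx_list([s.band.span for s in lay.slices], [0.4, 0.6])

    def test_spacing_shrinks_available_canvas(self):
        lay = allocate_bands([Interval(0, 2), Interval(4, 10)], [1.0], 0.04)
        approx_list([s.band.span for s in lay.slices], [0.24, 0.72])
        assert lay.slices[1].band.lo == pytest.approx(0.28)
        assert lay.slices[1].band.hi == pytest.approx(1.0)

    def test_infeasible_spacing_rejected(self):
        slices = partition(RANGE, [Interval(i + 0.1, i + 0.9) for i in range(5)])
        with pytest.raises(LayoutInfeasibleError):
            allocate_bands(slices, [1.0] * 5, 0.2)


class TestCutLayout:
    def test_equal_weights_zoom_upper_slice(self):
        lay = cut_layout(RANGE, [6], [1, 1], 0.0)
        assert [(s.data.lo, s.data.hi) for s in lay.slices] == [(0, 6), (6, 10)]
        approx_list([s.band.lo for s in lay.slices], [0.0, 0.5])
        approx_list([s.zoom for s in lay.slices], [1 / 12, 1 / 8])

    def test_proportional_weights_reproduce_spans(self):
        lay = cut_layout(RANGE, [6], "proportional", 0.0)
        approx_list([s.band.hi for s in lay.slices], [0.6, 1.0])
        # proportional means constant zoom: no magnification anywhere
        zooms = [s.zoom for s in lay.slices]
        assert zooms[0] == pytest.approx(zooms[1])

    def test_three_slices_explicit_weights(self):
        lay = cut_layout(RANGE, [2, 6], [1, 2, 1], 0.0)
        approx_list([s.band.span for s in lay.slices], [0.25, 0.5, 0.25])
        # cut slices are contiguous
        for a, b in zip(lay.slices, lay.slices[1:]):
            assert a.data.hi == b.data.lo


class TestWrap:
    def test_equal_split(self):
        out = wrap_partition(Interval(0, 100), 4)
        assert out == [Interval(0, 25), Interval(25, 50), Interval(50, 75), Interval(75, 100)]
        assert wrap_partition(Interval(0, 100), 1) == [Interval(0, 100)]

    def test_non_divisible_split_conserves_range(self):
        out = wrap_partition(Interval(0, 7), 3)
        widths = [iv.span for iv in out]
        approx_list(widths, [7 / 3] * 3, tol=1e-12 * 7)
        assert out[0].lo == 0 and out[-1].hi == 7
        for a, b in zip(out, out[1:]):
            assert a.hi == b.lo

    def test_invalid_rows_rejected(self):
        with pytest.raises(Exception):
            wrap_partition(Interval(0, 1), 0)

    def test_wrap_layout_rows_map_to_full_width(self):
        lay = wrap_layout(Interval(0, 100), 4)
        assert lay.mode == "wrap"
        for s in lay.slices:
            assert (s.band.lo, s.band.hi) == (0.0, 1.0)


@pytest.fixture
def gap_layout():
    return allocate_bands([Interval(0, 2), Interval(4, 10)], [1.0], 0.0)


class TestTransform:
    def test_forward_examples(self, gap_layout):
        assert data_to_canvas(1, gap_layout) == pytest.approx(0.125)
        assert data_to_canvas(7, gap_layout) == pytest.approx(0.625)
        assert data_to_canvas(3, gap_layout) is IN_GAP
        assert data_to_canvas(-1, gap_layout) is OUT_OF_RANGE
        assert data_to_canvas(11, gap_layout) is OUT_OF_RANGE

    def test_gap_boundaries_map_to_band_edges(self, gap_layout):
        assert data_to_canvas(2, gap_layout) == pytest.approx(0.25)
        assert data_to_canvas(4, gap_layout) == pytest.approx(0.25)

    def test_nonfinite_rejected(self, gap_layout):
        with pytest.raises(InvalidDatumError):
            data_to_canvas(float("nan"), gap_layout)

    def test_inverse_examples(self, gap_layout):
        assert canvas_to_data(0.125, gap_layout) == pytest.approx(1.0)
        assert canvas_to_data(0.625, gap_layout) == pytest.approx(7.0)
        with pytest.raises(Exception):
            canvas_to_data(1.5, gap_layout)

    def test_between_panels_sentinel(self):
        lay = allocate_bands([Interval(0, 2), Interval(4, 10)], [1.0], 0.04)
        assert canvas_to_data(0.26, lay) is BETWEEN_PANELS

    def test_identity_limit_is_plain_linear_rescale(self):
        lay = allocate_bands([RANGE], [], 0.0)
        assert lay.mode == "identity"
        assert (lay.slices[0].band.lo, lay.slices[0].band.hi) == (0.0, 1.0)
        for x in np.linspace(0, 10, 101):
            assert abs(data_to_canvas(x, lay) - x / 10) <= 1e-12


class TestLayoutProperties:
    """Conservation, monotonicity, round-trip, zoom laws on random layouts."""

    N_LAYOUTS = 150

    def test_conservation_monotonicity_roundtrip(self, rng):
        for _ in range(self.N_LAYOUTS):
            lay = random_break_layout(rng)
            total = sum(s.band.span for s in lay.slices) + lay.space * (lay.n - 1)
            assert abs(total - 1.0) <= 1e-9
            span = lay.total_range.span
            xs = np.linspace(lay.total_range.lo, lay.total_range.hi, 200)
            mask = visible_mask(lay, xs)
            vis = xs[mask]
            cs = np.array([data_to_canvas(x, lay) for x in vis])
            assert np.all(np.diff(cs) > 0)  # strictly monotone
            back = np.array([canvas_to_data(c, lay) for c in cs])
            assert np.max(np.abs(back - vis)) <= 1e-9 * span

    def test_anchor_interpolation_oracle(self, rng):
        for _ in range(30):
            lay = random_break_layout(rng)
            xs = np.arange(lay.total_range.lo, lay.total_range.hi,
                           1e-3 * lay.total_range.span)
            mask = visible_mask(lay, xs)
            expected = anchor_interp_transform(lay, xs[mask])
            got = np.array([data_to_canvas(x, lay) for x in xs[mask]])
            assert np.max(np.abs(got - expected)) <= 1e-9

    def test_zoom_monotonicity(self, rng):
        for _ in range(50):
            lay = random_break_layout(rng)
            if lay.n < 2:
                continue
            slices = [s.data for s in lay.slices]
            scales = [s.band.span / s.data.span for s in lay.slices[1:]]
            # recover scales relative to slice 0's zoom
            base = lay.slices[0].zoom
            scales = [z / base for z in scales]
            i = int(rng.integers(0, lay.n - 1))
            bumped = list(scales)
            bumped[i] *= 2
            lay2 = allocate_bands(slices, bumped, lay.space, mode="break")
            assert lay2.slices[i + 1].band.span > lay.slices[i + 1].band.span
            for j in range(lay.n):
                if j != i + 1:
                    assert lay2.slices[j].band.span < lay.slices[j].band.span
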