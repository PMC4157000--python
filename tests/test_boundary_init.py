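import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cimt.boundary_init import (
    Boundary,
    analyze_histogram,
    close_gaps,
    edge_map,
    estimate_lii,
    estimate_mai,
    segment_binary,
    trace_rough_lii,
)
from cimt.errors import InitializationFailure, ValidationError
from cimt.synthetic import PhantomSpec, generate_phantom, sloped_profile

from conftest import gray


def crossing_image(crossings, n_rows=None, low=0.0, high=0.5):
    """Image whose first super-threshold row in column j is crossings[j];
    None means the column never crosses."""
    n_rows = n_rows or (max(c for c in crossings if c is not None) + 4)
    px = np.full((n_rows, len(crossings)), low)
    for j, c in enumerate(crossings):
        if c is not None:
            px[c:, j] = high
    return gray(px)


# Hand-executed traces of the four-step threshold-crossing tracker:
# +1 when the new crossing is deeper than the current boundary row,
# -1 when shallower, re-anchor on equality.
TRACE_CASES = [
    ([10, 10, 10, 10], [10, 10, 10, 10]),
    ([5, 9, 9, 9], [5, 6, 7, 8]),
    ([8, 6, 6], [8, 7, 6]),
    ([3, 4, 5, 6], [3, 4, 5, 6]),
    ([9, 8, 7, 6], [9, 8, 7, 6]),
    ([5, 5, 8, 5], [5, 5, 6, 5]),
    ([10, 2, 10, 10], [10, 9, 10, 10]),
    ([1, 3, 3, 3, 3], [1, 2, 3, 3, 3]),
    ([6, 6, 6, 9, 9, 9, 9], [6, 6, 6, 7, 8, 9, 9]),
    ([4, 7, 2, 7, 4], [4, 5, 4, 5, 4]),
    ([12, 12, 11, 11, 12, 12], [12, 12, 11, 11, 12, 12]),
    ([2, 9, 9, 9, 9, 9, 9, 9, 2], [2, 3, 4, 5, 6, 7, 8, 9, 8]),
]


class TestRoughTrace:
    @pytest.mark.parametrize("crossings, expected", TRACE_CASES)
    def test_reproduces_hand_executed_traces(self, crossings, expected):
        boundary = trace_rough_lii(crossing_image(crossings), 0.1)
        np.testing.assert_array_equal(boundary.rows, expected)

    def test_missing_column_carries_boundary_forward(self):
        boundary = trace_rough_lii(crossing_image([5, None, 5, 5]), 0.1)
        np.testing.assert_array_equal(boundary.rows, [5, 5, 5, 5])

    def test_all_columns_below_threshold_fails(self):
        with pytest.raises(InitializationFailure):
            trace_rough_lii(gray(np.zeros((8, 6))), 0.1)

    def test_threshold_domain_enforced(self):
        with pytest.raises(ValidationError):
            trace_rough_lii(gray(np.zeros((8, 6))), 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=19), min_size=2, max_size=25)
    )
    def test_trace_is_eight_neighborhood_continuous(self, crossings):
        boundary = trace_rough_lii(crossing_image(crossings, n_rows=24), 0.1)
        assert np.abs(np.diff(boundary.rows)).max() <= 1


class TestSegmentAndClose:
    def test_all_dark_roi_gives_empty_mask(self):
        assert not segment_binary(gray(np.zeros((6, 6))), 0.1).any()

    def test_trimodal_phantom_mask_separates_layers(self):
        img, gt_lii, gt_mai = generate_phantom(PhantomSpec(imt_mm=0.7))
        # threshold in the lumen/intima valley, above the media mean
        mask = segment_binary(img, 0.25)
        col = img.n_cols // 2
        lii, mai = gt_lii.rows[col], gt_mai.rows[col]
        intima_mid = int(lii + 0.25 * (mai - lii))
        media_mid = int(lii + 0.75 * (mai - lii))
        assert mask[intima_mid, col]  # intima band
        assert mask[int(mai) + 3, col]  # adventitia
        assert not mask[int(lii) - 3, col]  # lumen
        assert not mask[media_mid, col]  # media

    def test_gap_narrower_than_element_is_bridged(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[10:13, :] = True
        mask[:, 18:24] = False  # 6-px gap
        closed = close_gaps(mask, 15)
        assert closed[10:13, :].all()

    def test_full_mask_unchanged(self):
        mask = np.ones((20, 20), dtype=bool)
        np.testing.assert_array_equal(close_gaps(mask, 15), mask)

    def test_gap_wider_than_element_not_fully_bridged(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[10:13, :] = True
        mask[:, 20:40] = False  # 20-px gap > element span
        closed = close_gaps(mask, 15)
        assert not closed[10:13, 20:40].all()

    def test_closing_does_not_fabricate_foreground_at_borders(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[3:6, :] = True  # band close to the top border
        closed = close_gaps(mask, 15)
        assert not closed[:3, :].any()


class TestEstimateLii:
    def test_horizontal_intima_recovered(self):
        img, gt_lii, _ = generate_phantom(PhantomSpec(imt_mm=0.7))
        roi = gray(img.pixels[100:150, :], img.pixel_density)
        est = estimate_lii(roi, 0.1, 15)
        assert np.abs(est.rows - (gt_lii.rows - 100)).max() <= 1.5

    def test_intima_gap_bridged_within_two_pixels(self):
        spec = PhantomSpec(imt_mm=0.7, intima_gap_cols=(180, 185))
        img, gt_lii, _ = generate_phantom(spec)
        roi = gray(img.pixels[100:150, :], img.pixel_density)
        est = estimate_lii(roi, 0.1, 15)
        gap = slice(180, 185)
        assert np.abs(est.rows[gap] - (gt_lii.rows[gap] - 100)).max() <= 2

    def test_sloped_boundary_tracked(self):
        spec = PhantomSpec(imt_mm=0.7, lii_row=sloped_profile(118, 0.02, 384))
        img, gt_lii, _ = generate_phantom(spec)
        roi = gray(img.pixels[100:150, :], img.pixel_density)
        est = estimate_lii(roi, 0.1, 15)
        assert np.abs(est.rows - (gt_lii.rows - 100)).max() <= 1.5

    def test_mostly_empty_roi_fails(self):
        px = np.zeros((40, 30))
        px[20:, :5] = 0.5  # only 5 of 30 columns ever cross
        with pytest.raises(InitializationFailure):
            estimate_lii(gray(px), 0.1, 3)


class TestEdgeMap:
    def test_constant_image_maps_to_exact_zero(self):
        emap = edge_map(gray(np.full((20, 15), 0.4)))
        np.testing.assert_array_equal(emap.values, 0.0)

    def test_step_response_peaks_at_step_row(self):
        px = np.zeros((30, 12))
        px[15:, :] = 1.0  # dark above, bright below
        emap = edge_map(gray(px))
        peaks = emap.values.argmax(axis=0)
        assert np.abs(peaks - 15).max() <= 1
        assert emap.values[15, 5] > 0  # dark-to-bright is positive

    def test_linear_in_the_image(self):
        rng = np.random.default_rng(21)
        a_px, b_px = rng.random((16, 14)), rng.random((16, 14))
        lhs = edge_map(gray(np.clip(0.6 * a_px + 0.3 * b_px, 0, 1))).values
        rhs = 0.6 * edge_map(gray(a_px)).values + 0.3 * edge_map(gray(b_px)).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_vertical_flip_negates_response_for_odd_kernel(self):
        rng = np.random.default_rng(22)
        px = rng.random((20, 10))
        fwd = edge_map(gray(px), kernel_size=11).values
        flipped = edge_map(gray(px[::-1].copy()), kernel_size=11).values
        np.testing.assert_allclose(flipped, -fwd[::-1], atol=1e-12)


class TestEstimateMai:
    def _flat_emap_with_line(self, n_rows, n_cols, line_rows, value=1.0):
        vals = np.zeros((n_rows, n_cols))
        vals[line_rows, np.arange(n_cols)] = value
        return vals

    def test_finds_known_parallel_offset(self):
        from cimt.boundary_init import EdgeMap

        n_rows, n_cols = 40, 30
        lii = Boundary(0, np.full(n_cols, 10.0))
        vals = self._flat_emap_with_line(n_rows, n_cols, np.full(n_cols, 22, dtype=int))
        roi = gray(np.zeros((n_rows, n_cols)), density=16.66)
        mai, delta = estimate_mai(lii, EdgeMap(vals), roi)
        assert delta == 12
        np.testing.assert_array_equal(mai.rows, 22.0)

    def test_displacement_search_range_at_reference_density(self):
        # 0.4 mm -> 7 px and 1.4 mm -> 23 px at 16.66 px/mm: an edge line
        # at offset 6 is out of reach, the best in-range line at 7 wins.
        from cimt.boundary_init import EdgeMap

        n_rows, n_cols = 40, 20
        lii = Boundary(0, np.full(n_cols, 5.0))
        vals = np.zeros((n_rows, n_cols))
        vals[11, :] = 5.0  # offset 6: outside [7, 23]
        vals[12, :] = 1.0  # offset 7: reachable
        roi = gray(np.zeros((n_rows, n_cols)), density=16.66)
        _, delta = estimate_mai(lii, EdgeMap(vals), roi)
        assert delta == 7

    def test_tie_breaks_to_smaller_displacement(self):
        from cimt.boundary_init import EdgeMap

        n_rows, n_cols = 40, 20
        lii = Boundary(0, np.full(n_cols, 5.0))
        vals = np.zeros((n_rows, n_cols))
        vals[14, :] = 1.0  # offset 9
        vals[20, :] = 1.0  # offset 15, equal sum
        roi = gray(np.zeros((n_rows, n_cols)), density=16.66)
        _, delta = estimate_mai(lii, EdgeMap(vals), roi)
        assert delta == 9

    def test_output_is_exact_translate_of_lii(self):
        from cimt.boundary_init import EdgeMap

        rng = np.random.default_rng(23)
        n_rows, n_cols = 60, 25
        lii = Boundary(0, 10.0 + np.arange(n_cols) * 0.2)
        vals = rng.random((n_rows, n_cols))
        roi = gray(np.zeros((n_rows, n_cols)), density=16.66)
        mai, delta = estimate_mai(lii, EdgeMap(vals), roi)
        np.testing.assert_allclose(mai.rows - lii.rows, delta)


class TestHistogram:
    def test_trimodal_roi_valleys_between_modes(self):
        # three-band ROI with modes at 0.05 / 0.45 / 0.85 and small spread
        rng = np.random.default_rng(31)
        bands = np.concatenate(
            [np.full(20, 0.05), np.full(12, 0.45), np.full(18, 0.85)]
        )
        px = np.clip(bands[:, None] + 0.02 * rng.standard_normal((50, 200)), 0, 1)
        roi = gray(px)
        hist = analyze_histogram(roi)
        assert hist.t1 is not None and hist.t2 is not None
        assert 0.05 < hist.t1 < 0.45
        assert 0.45 < hist.t2 < 0.85
        assert hist.t1 < hist.t2

    def test_constant_image_has_no_valleys(self):
        hist = analyze_histogram(gray(np.full((20, 20), 0.5)))
        assert hist.t1 is None
        assert hist.ambiguous

    def test_missing_intima_roi_is_ambiguous(self):
        img, gt_lii, gt_mai = generate_phantom(
            PhantomSpec(imt_mm=0.7, missing_intima=True)
        )
        center = int((gt_lii.rows[0] + gt_mai.rows[0]) / 2)
        roi = gray(img.pixels[center - 20 : center + 21, :], img.pixel_density)
        hist = analyze_histogram(roi)
        assert hist.ambiguous
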