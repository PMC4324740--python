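"""Gloss extraction: subtraction, Otsu thresholding and the two indices."""

import numpy as np
import pytest

from tonguegloss import (
    CalibrationModel,
    FramePair,
    detect_gloss,
    gloss_degree,
    measure_pair,
    otsu_threshold,
    subtract_pair,
)
from tonguegloss.errors import DegenerateHistogramError, EmptyRoiError, ShapeMismatchError
from tonguegloss.gloss import REC709_WEIGHTS
from tonguegloss.synthetic import TongueSceneParams, make_pair, tongue_mask_from_params

from conftest import scene_with_fraction


def brute_force_otsu(values, n_levels=256):
    """Exhaustive between-class-variance search, smallest argmax (test oracle)."""
    levels = np.clip(np.floor(np.asarray(values, float).ravel()), 0, n_levels - 1).astype(int)
    counts = np.bincount(levels, minlength=n_levels)
    best_t, best_v = None, -1.0
    total = counts.sum()
    for t in range(n_levels - 1):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * counts[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, n_levels) * counts[t + 1 :]).sum() / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


def _pair(gloss, nongloss, mask=None, t=0.0):
    gloss = np.asarray(gloss, float)
    if mask is None:
        mask = np.ones(gloss.shape[:2], bool)
    return FramePair(gloss, np.asarray(nongloss, float), mask, timestamp_s=t)


class TestSubtractPair:
    def test_identical_frames_give_zero(self):
        frame = np.random.default_rng(0).uniform(0, 255, (6, 7, 3))
        assert np.all(subtract_pair(_pair(frame, frame)) == 0)

    def test_constant_offset_inside_mask(self):
        nongloss = np.full((10, 10, 3), 50.0)
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        diff = subtract_pair(_pair(nongloss + 40.0, nongloss, mask))
        assert np.allclose(diff[mask], 40.0)
        assert np.all(diff[~mask] == 0)

    def test_matches_clamped_per_pixel_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 255, (12, 9, 3))
        n = rng.uniform(0, 255, (12, 9, 3))
        diff = subtract_pair(_pair(g, n))
        oracle = np.maximum(g - n, 0.0) @ REC709_WEIGHTS
        np.testing.assert_allclose(diff, oracle, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            _pair(np.zeros((4, 4, 3)), np.zeros((5, 4, 3)))


class TestOtsuThreshold:
    def test_two_cluster_example(self):
        """{1,1,2} vs {8,9,9}: any level in [2,8) separates; smallest is returned."""
        values = [1, 1, 2, 8, 9, 9]
        t = otsu_threshold(values)
        assert t == 2.0
        assert t == brute_force_otsu(values)

    def test_bimodal_extremes_smallest_argmax(self):
        """0/255 image: every split is equivalent, so the smallest level wins."""
        values = np.array([0] * 40 + [255] * 60)
        assert otsu_threshold(values) == 0.0 == brute_force_otsu(values)

    def test_gaussian_mixture_threshold_separates_modes(self):
        """On a well-separated two-Gaussian mixture the threshold sits in the
        gap (smallest-argmax places it at the low edge) and classifies ≥99%
        of the draws by mode."""
        rng = np.random.default_rng(12)
        low = rng.normal(30, 5, 500)
        high = rng.normal(200, 10, 500)
        values = np.concatenate([low, high])
        t = otsu_threshold(values)
        assert 30 < t < 200
        misclassified = np.count_nonzero(low > t) + np.count_nonzero(high <= t)
        assert misclassified / values.size < 0.01
        assert t == brute_force_otsu(values)

    @pytest.mark.parametrize("case", range(40))
    def test_matches_exhaustive_search_on_random_histograms(self, case):
        """Exact agreement with brute force on unimodal, bimodal and near-degenerate data."""
        rng = np.random.default_rng(1000 + case)
        kind = case % 4
        if kind == 0:  # unimodal
            values = rng.normal(rng.uniform(30, 200), rng.uniform(2, 30), 400)
        elif kind == 1:  # bimodal
            values = np.concatenate(
                [rng.normal(rng.uniform(10, 80), rng.uniform(2, 10), 300),
                 rng.normal(rng.uniform(120, 240), rng.uniform(2, 15), 200)]
            )
        elif kind == 2:  # degenerate-adjacent: two neighbouring levels
            base = rng.integers(0, 254)
            values = rng.choice([base, base + 1], 100)
            if len(np.unique(values)) < 2:
                values[0] = base + 1
        else:  # sparse random integer levels
            values = rng.integers(0, 256, 50).astype(float)
            if len(np.unique(np.floor(values))) < 2:
                values[0] += 1
        assert otsu_threshold(values) == brute_force_otsu(values)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full(100, 7.0))

    def test_threshold_lies_within_value_range(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(20, 90, 300)
        t = otsu_threshold(values)
        assert np.floor(values.min()) <= t < values.max()


class TestDetectGloss:
    def test_identical_frames_zero_ratio(self):
        frame = np.full((20, 20, 3), 100.0)
        m = detect_gloss(_pair(frame, frame))
        assert m.area_ratio_pct == 0.0
        assert not m.gloss_mask.any()

    def test_synthetic_five_percent_recovered(self, five_pct_pair):
        pair, speckle, params = five_pct_pair
        m = detect_gloss(pair)
        truth = 100.0 * params.speckle_px / np.count_nonzero(pair.tongue_mask)
        assert m.area_ratio_pct == pytest.approx(truth, abs=0.2)
        inter = np.count_nonzero(m.gloss_mask & speckle)
        union = np.count_nonzero(m.gloss_mask | speckle)
        assert inter / union >= 0.95

    @pytest.mark.parametrize("amplitude", [40.0, 80.0, 120.0, 160.0, 200.0])
    def test_ratio_stable_under_amplitude_sweep(self, amplitude):
        """The threshold adapts: the area index does not depend on gloss strength."""
        params = scene_with_fraction(5.0, seed=21)
        params.speckle_amplitude = amplitude
        pair, _ = make_pair(params)
        m = detect_gloss(pair)
        assert m.area_ratio_pct == pytest.approx(5.0, abs=0.5)

    def test_noise_only_pair_reports_no_gloss(self):
        """Without speckle the pair differs only by sensor noise: ratio ≤ 0.5%."""
        for seed in range(5):
            params = TongueSceneParams(seed=seed, speckle_px=0)
            pair, _ = make_pair(params)
            m = detect_gloss(pair)
            assert m.area_ratio_pct <= 0.5

    def test_gloss_mask_subset_of_tongue(self, five_pct_pair):
        pair, _, _ = five_pct_pair
        m = detect_gloss(pair)
        assert not np.any(m.gloss_mask & ~pair.tongue_mask)

    def test_invariant_to_common_constant_offset(self, five_pct_pair):
        """Adding the same constant to both frames cancels in the subtraction."""
        pair, _, _ = five_pct_pair
        shifted = FramePair(
            pair.gloss_frame.astype(float) + 17.0,
            pair.nongloss_frame.astype(float) + 17.0,
            pair.tongue_mask,
        )
        assert detect_gloss(shifted).area_ratio_pct == detect_gloss(pair).area_ratio_pct

    def test_ratio_monotone_in_speckle_area(self):
        ratios = []
        for frac in (1.0, 3.0, 6.0, 12.0):
            pair, _ = make_pair(scene_with_fraction(frac, seed=33))
            ratios.append(detect_gloss(pair).area_ratio_pct)
        assert all(r1 > r0 for r0, r1 in zip(ratios, ratios[1:]))


class TestGlossDegree:
    @staticmethod
    def _gray_for_L(L):
        """Gray level whose identity-calibration L* (white 255) equals L."""
        return 255.0 * ((L + 16.0) / 116.0) ** 3

    def test_identical_frames_zero(self, identity_model):
        frame = np.full((10, 10, 3), 90.0)
        roi = np.ones((10, 10), bool)
        assert gloss_degree(_pair(frame, frame), roi, identity_model) == 0.0

    def test_closed_form_L70_minus_L50(self, identity_model):
        g = np.full((10, 10, 3), self._gray_for_L(70.0))
        n = np.full((10, 10, 3), self._gray_for_L(50.0))
        roi = np.zeros((10, 10), bool)
        roi[3:7, 3:7] = True
        delta = gloss_degree(_pair(g, n), roi, identity_model)
        assert delta == pytest.approx(20.0, abs=1e-9)

    def test_antisymmetric_under_frame_swap(self, identity_model):
        rng = np.random.default_rng(8)
        g = rng.uniform(50, 200, (12, 12, 3))
        n = rng.uniform(50, 200, (12, 12, 3))
        roi = np.ones((12, 12), bool)
        mask = np.ones((12, 12), bool)
        fwd = gloss_degree(FramePair(g, n, mask), roi, identity_model)
        rev = gloss_degree(FramePair(n, g, mask), roi, identity_model)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_empty_roi_rejected(self, identity_model):
        frame = np.zeros((5, 5, 3))
        with pytest.raises(EmptyRoiError):
            gloss_degree(_pair(frame, frame), np.zeros((5, 5), bool), identity_model)


def test_measure_pair_combines_both_indices(five_pct_pair, identity_model):
    pair, _, _ = five_pct_pair
    roi = np.zeros(pair.tongue_mask.shape, bool)
    roi[90:110, 120:140] = True
    m = measure_pair(pair, roi, identity_model)
    assert m.area_ratio_pct > 0
    assert m.delta_L_star is not None
    assert m.delta_L_star == gloss_degree(pair, roi, identity_model)


def test_measurement_json_export(tmp_path, five_pct_pair, identity_model):
    pair, _, _ = five_pct_pair
    roi = np.zeros(pair.tongue_mask.shape, bool)
    roi[95:105, 125:135] = True
    m = measure_pair(pair, roi, identity_model)
    path = tmp_path / "meas.json"
    m.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["area_ratio_pct"] == pytest.approx(m.area_ratio_pct, abs=0.01)
    assert payload["glossy_pixels"] == int(np.count_nonzero(m.gloss_mask))
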