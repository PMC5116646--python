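"""Fusion weights, blending limits, and prior construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import mvkvmar as m
from mvkvmar.fusion import DEFAULT_SIGMA_MM


def grid(values, spacing=1.0):
    return m.ImageGrid(np.asarray(values, dtype=float), pixel_spacing=(spacing, spacing))


class TestSegmentMetal:
    def test_threshold_is_inclusive_at_3000(self):
        img = grid([[2900.0, 3100.0]])
        mask = m.segment_metal(img)
        assert mask.mask.tolist() == [[False, True]]
        assert mask.threshold_hu == 3000.0

    def test_air_image_gives_empty_mask(self):
        assert m.segment_metal(grid(np.full((8, 8), -1000.0))).empty

    def test_small_component_removal(self):
        values = np.zeros((16, 16))
        values[2, 2] = 5000.0  # isolated noise spike
        values[8:12, 8:12] = 5000.0
        mask = m.segment_metal(grid(values), min_area_px=4)
        assert not mask.mask[2, 2]
        assert mask.mask[9, 9]

    def test_metal_area_matches_analytic_ellipse_minus_hole(self, study):
        expected = np.pi * 4.97 * 3.58 / 4 - np.pi * (1.81 / 2) ** 2
        px_cm2 = (study.mv.pixel_spacing[0] / 10.0) ** 2
        # exact on the artifact-free rasterized MV truth ...
        truth_mv = m.rasterize(
            study.spec, study.mv.shape, study.mv.pixel_spacing[0], "MV"
        )
        area_truth = m.segment_metal(truth_mv).mask.sum() * px_cm2
        assert area_truth == pytest.approx(expected, rel=0.02)
        # ... and within 10% on the simulated scan, whose 1.5 mm detector
        # blur erodes the thin ellipse tips below the 3000 HU threshold
        area_sim = m.segment_metal(study.mv).mask.sum() * px_cm2
        assert area_sim == pytest.approx(expected, rel=0.10)


class TestRelativeDeviation:
    def test_equal_images_give_zero(self):
        img = grid(np.full((4, 4), 123.0))
        assert np.all(m.relative_deviation(img, img) == 0.0)

    def test_direct_evaluation(self):
        r = m.relative_deviation(grid([[300.0]]), grid([[100.0]]))
        assert r[0, 0] == pytest.approx(0.5)

    def test_zero_denominator_replaced_by_one(self):
        r = m.relative_deviation(grid([[50.0]]), grid([[-50.0]]))
        assert r[0, 0] == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.relative_deviation(grid(np.zeros((4, 4))), grid(np.zeros((5, 5))))


class TestDeviationWeight:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.05, 0.0), (0.225, 0.5), (0.40, 1.0), (1.40, 1.0)],
    )
    def test_ramp_values(self, r, expected):
        w = m.deviation_weight(np.array([[r]]), r_lo=0.05, r_hi=0.40)
        assert w[0, 0] == pytest.approx(expected)

    def test_monotone_in_r(self):
        r = np.linspace(0, 2, 100)[None]
        w = m.deviation_weight(r)
        assert np.all(np.diff(w[0]) >= 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_bad_ramp_rejected(self):
        with pytest.raises(ValueError):
            m.deviation_weight(np.zeros((2, 2)), r_lo=0.5, r_hi=0.5)


class TestDistanceWeight:
    def test_empty_mask_warns_and_returns_zero(self):
        mask = m.MetalMask(np.zeros((8, 8), dtype=bool))
        with pytest.warns(UserWarning):
            w_d = m.distance_weight(mask, (1.0, 1.0), sigma_mm=5.0)
        assert np.all(w_d == 0.0)

    def test_single_pixel_peaks_at_metal_and_decays_radially(self):
        mask = np.zeros((33, 33), dtype=bool)
        mask[16, 16] = True
        w_d = m.distance_weight(m.MetalMask(mask), (1.0, 1.0), sigma_mm=3.0)
        assert w_d[16, 16] == pytest.approx(1.0)
        assert w_d[16, 20] > w_d[16, 26] > 0
        assert np.all((w_d >= 0) & (w_d <= 1))

    def test_decay_with_distance_on_phantom_mask(self, study):
        metal = m.segment_metal(study.mv)
        w_d = m.distance_weight(metal, study.mv.pixel_spacing, sigma_mm=10.0)
        from scipy.ndimage import distance_transform_edt

        dist_mm = distance_transform_edt(
            ~metal.mask, sampling=study.mv.pixel_spacing
        )
        near = w_d[(dist_mm > 4) & (dist_mm < 6)].mean()
        far = w_d[(dist_mm > 19) & (dist_mm < 21)].mean()
        assert near > far

    def test_unity_on_metal_pixels(self, study):
        metal = m.segment_metal(study.mv)
        w_d = m.distance_weight(metal, study.mv.pixel_spacing, DEFAULT_SIGMA_MM)
        assert w_d[metal.mask].max() == pytest.approx(1.0)


class TestFuse:
    def _weights(self, w, w_d):
        return m.WeightMaps(w=w, w_d=w_d)

    def test_zero_distance_weight_returns_kv_exactly(self, study):
        shape = study.kv.shape
        weights = self._weights(np.ones(shape) * 0.7, np.zeros(shape))
        fused = m.fuse(study.kv, study.mv, weights)
        assert np.array_equal(fused.values, study.kv.values)

    def test_full_weights_return_mv(self, study):
        shape = study.kv.shape
        weights = self._weights(np.ones(shape), np.ones(shape))
        fused = m.fuse(study.kv, study.mv, weights)
        assert np.allclose(fused.values, study.mv.values)

    def test_equal_inputs_invariant_under_any_weights(self):
        rng = np.random.default_rng(3)
        img = grid(rng.normal(0, 300, (16, 16)))
        weights = self._weights(rng.random((16, 16)), rng.random((16, 16)))
        fused = m.fuse(img, img, weights)
        assert np.allclose(fused.values, img.values)

    @given(
        kv=hnp.arrays(np.float64, (6, 6), elements=st.floats(-1000, 4000)),
        mv=hnp.arrays(np.float64, (6, 6), elements=st.floats(-1000, 4000)),
        w=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
        w_d=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
    )
    def test_convexity_bound(self, kv, mv, w, w_d):
        fused = m.fuse(grid(kv), grid(mv), m.WeightMaps(w=w, w_d=w_d)).values
        lo = np.minimum(kv, mv) - 1e-9
        hi = np.maximum(kv, mv) + 1e-9
        assert np.all(fused >= lo) and np.all(fused <= hi)

    def test_mv_share_monotone_in_r(self):
        """Raising R at one pixel (others fixed) never lowers the MV share w*w_d."""
        r = np.linspace(0, 1, 50)
        w = m.deviation_weight(r[None])
        share = w * 0.8  # any fixed w_d
        assert np.all(np.diff(share[0]) >= 0)


class TestMakePrior:
    def test_empty_mask_leaves_metal_free_fused_unchanged(self, study):
        fused = study.kv.with_values(np.clip(study.kv.values, None, 2500.0))
        prior = m.make_prior(fused, m.MetalMask(np.zeros(fused.shape, bool)))
        assert np.array_equal(prior.values, fused.values)

    def test_all_metal_gives_constant_fill(self):
        img = grid(np.full((8, 8), 9000.0))
        prior = m.make_prior(img, m.MetalMask(np.ones((8, 8), bool)), fill_hu=0.0)
        assert np.all(prior.values == 0.0)

    def test_prior_contains_no_metal_valued_pixels(self, fusion_corrected):
        assert fusion_corrected.prior.values.max() < 3000.0
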