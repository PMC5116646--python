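"""Trace extraction, surrogate replacement, and the MAR method family."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mvkvmar as m
from mvkvmar.mar import TraceMask, interpolate_trace, nmar_replace, nmar_prior_from_limar
from conftest import as_sinogram, brute_force_replace, random_sinogram_case


class TestTraceMask:
    def test_segments_reconstruct_mask_exactly(self):
        rng = np.random.default_rng(7)
        mask = rng.random((12, 20)) < 0.35
        trace = TraceMask.from_mask(mask)
        rebuilt = np.zeros_like(mask)
        for view, start, stop in trace.segments:
            rebuilt[view, start : stop + 1] = True
        assert np.array_equal(rebuilt, mask)

    def test_segment_boundaries_outside_mask(self):
        mask = np.zeros((4, 10), dtype=bool)
        mask[1, 3:6] = True
        mask[2, 0:2] = True  # touches the detector edge
        trace = TraceMask.from_mask(mask)
        for view, start, stop in trace.segments:
            if start > 0:
                assert not mask[view, start - 1]
            if stop < 9:
                assert not mask[view, stop + 1]


class TestMetalTrace:
    def test_empty_metal_gives_empty_trace(self, study):
        trace = m.metal_trace(
            m.MetalMask(np.zeros(study.kv.shape, bool)), study.sino_kv.geometry
        )
        assert trace.empty

    def test_single_pixel_casts_one_short_segment_per_view(self):
        img = m.ImageGrid(np.zeros((64, 64)), pixel_spacing=(2.0, 2.0))
        geom = m.ProjectionGeometry.for_image(img, n_views=45)
        mask = np.zeros((64, 64), bool)
        mask[32, 32] = True
        trace = m.metal_trace(m.MetalMask(mask), geom)
        per_view = np.zeros(45, int)
        for view, start, stop in trace.segments:
            per_view[view] += 1
            assert stop - start <= 2
        assert np.all(per_view == 1)

    def test_convex_metal_casts_single_segment_per_view(self, study):
        metal = m.segment_metal(study.mv)
        # fill the central hole so the mask is convex
        from scipy.ndimage import binary_fill_holes

        convex = m.MetalMask(binary_fill_holes(metal.mask))
        trace = m.metal_trace(convex, study.sino_kv.geometry)
        per_view = np.zeros(study.sino_kv.n_views, int)
        for view, _, _ in trace.segments:
            per_view[view] += 1
        assert np.all(per_view == 1)


class TestReplaceTrace:
    def test_matching_boundaries_reduce_to_prior(self):
        p_kv = as_sinogram([[1.0, 2.0, 9.0, 9.0, 2.0, 1.0]] * 2)
        p_prior = as_sinogram([[1.0, 2.0, 4.0, 4.0, 2.0, 1.0]] * 2)
        mask = np.zeros((2, 6), bool)
        mask[:, 2:4] = True
        out = m.replace_trace(p_kv, p_prior, TraceMask.from_mask(mask))
        assert np.array_equal(out.values, p_prior.values)

    def test_outside_trace_bit_identical(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p_kv, p_prior, mask = random_sinogram_case(rng)
            out = m.replace_trace(
                as_sinogram(p_kv), as_sinogram(p_prior), TraceMask.from_mask(mask)
            )
            assert np.array_equal(out.values[~mask], p_kv[~mask])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p_kv, p_prior, mask = random_sinogram_case(rng)
            out = m.replace_trace(
                as_sinogram(p_kv), as_sinogram(p_prior), TraceMask.from_mask(mask)
            )
            assert np.array_equal(out.values, brute_force_replace(p_kv, p_prior, mask))

    @given(data=st.data())
    def test_boundary_blend_equals_boundary_offsets(self, data):
        """At the virtual positions b = jj and b = jj+D+1 the blend equals the
        boundary offsets exactly, so P_cor is continuous with P_kv."""
        n = data.draw(st.integers(6, 16))
        start = data.draw(st.integers(1, n - 4))
        stop = data.draw(st.integers(start, n - 3))
        vals = data.draw(
            st.lists(st.floats(-50, 50), min_size=2 * n, max_size=2 * n)
        )
        p_kv = np.array(vals[:n])[None]
        p_prior = np.array(vals[n:])[None]
        jj, right = start - 1, stop + 1
        d = stop - start + 1
        off_l = p_kv[0, jj] - p_prior[0, jj]
        off_r = p_kv[0, right] - p_prior[0, right]
        blend_at = lambda b: ((right - b) * off_l + (b - jj) * off_r) / (d + 1)
        assert blend_at(jj) == pytest.approx(off_l)
        assert blend_at(right) == pytest.approx(off_r)


class TestLimarAndNmar:
    def test_limar_equals_replace_trace_with_zero_prior(self):
        rng = np.random.default_rng(17)
        p_kv, _, mask = random_sinogram_case(rng)
        sino = as_sinogram(p_kv)
        trace = TraceMask.from_mask(mask)
        zero = sino.with_values(np.zeros_like(p_kv))
        assert np.array_equal(
            interpolate_trace(sino, trace).values,
            m.replace_trace(sino, zero, trace).values,
        )

    def test_constant_rows_interpolate_to_constant(self):
        p = as_sinogram(np.full((3, 10), 7.5))
        mask = np.zeros((3, 10), bool)
        mask[:, 4:7] = True
        out = interpolate_trace(p, TraceMask.from_mask(mask))
        assert np.allclose(out.values, 7.5)

    def test_nmar_with_constant_prior_sinogram_equals_limar(self):
        rng = np.random.default_rng(19)
        p_kv, _, mask = random_sinogram_case(rng)
        sino = as_sinogram(p_kv)
        trace = TraceMask.from_mask(mask)
        const_prior = sino.with_values(np.full_like(p_kv, 2.0))  # exact binary scale
        out_nmar = nmar_replace(sino, const_prior, trace, epsilon=1e-2)
        out_limar = interpolate_trace(sino, trace)
        assert np.array_equal(out_nmar.values, out_limar.values)

    def test_empty_mask_is_round_trip_fixed_point(self, study):
        empty = m.MetalMask(np.zeros(study.kv.shape, bool))
        out = m.limar(study.kv, empty, sino_kv=study.sino_kv)
        base = m.fbp(study.sino_kv)
        assert np.allclose(out.values, base.values)

    def test_nmar_prior_flattens_tissue_classes(self):
        values = np.array([[-900.0, -800.0, 100.0, 200.0, 800.0]])
        img = m.ImageGrid(values, pixel_spacing=(1.0, 1.0))
        prior = nmar_prior_from_limar(img)
        assert prior.values[0, 0] == prior.values[0, 1] == pytest.approx(-850.0)
        assert prior.values[0, 2] == prior.values[0, 3] == pytest.approx(150.0)
        assert prior.values[0, 4] == 800.0  # dense pixels kept as-is


class TestReinsertMetal:
    def test_empty_and_full_masks(self):
        recon = m.ImageGrid(np.zeros((8, 8)), pixel_spacing=(1.0, 1.0))
        source = m.ImageGrid(np.full((8, 8), 5000.0), pixel_spacing=(1.0, 1.0))
        empty = m.MetalMask(np.zeros((8, 8), bool))
        full = m.MetalMask(np.ones((8, 8), bool))
        assert np.array_equal(m.reinsert_metal(recon, source, empty).values, recon.values)
        assert np.array_equal(m.reinsert_metal(recon, source, full).values, source.values)

    def test_corrected_metal_mean_equals_mv_metal_mean(self, fusion_corrected):
        metal = fusion_corrected.metal.mask
        assert fusion_corrected.corrected.values[metal].mean() == pytest.approx(
            fusion_corrected.pseudo_mv.values[metal].mean()
        )


class TestMarCorrect:
    def test_no_metal_degenerates_to_round_trip(self, study):
        no_metal = study.kv.with_values(np.clip(study.kv.values, None, 2000.0))
        mv_no_metal = study.mv.with_values(np.clip(study.mv.values, None, 2000.0))
        result = m.mar_correct(no_metal, mv_no_metal, sino_kv=study.sino_kv)
        assert result.metal.empty
        assert result.trace is None
        assert np.allclose(result.corrected.values, m.fbp(study.sino_kv).values)

    def test_intermediates_exposed(self, fusion_corrected):
        r = fusion_corrected
        assert r.used_measured_sinogram
        assert r.fused is not None and r.prior is not None
        assert r.sino_corrected.values.shape == r.sino_kv.values.shape
        # data fidelity: untouched bins are bit-identical
        outside = ~r.trace.mask
        assert np.array_equal(
            r.sino_corrected.values[outside], r.sino_kv.values[outside]
        )
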