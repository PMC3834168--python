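"""Synthetic phantom generator tests: geometry, forward model, lesions."""

import numpy as np
import pytest

import tractbench as tb
from tractbench import tensor
from tractbench.dwi import BSCALE, make_gradient_table
from tractbench.phantom import (BundleGeometry, LesionSpec, PhantomSpec,
                                rasterize, simulate_dwi)

from conftest import fit_pipeline


class TestStandardGeometry:
    def test_inventory(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        names = set(gt.bundles)
        assert names == {"cross_high", "cross_low", "bend",
                         "split_1", "split_2", "split_3"}
        for b in gt.bundles.values():
            assert b.mask.any()
            assert len(b.endpoint_labels) == 2

    def test_crossing_fractions_half_half(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        hi, lo = gt.bundles["cross_high"], gt.bundles["cross_low"]
        core = (hi.fraction > 0.49) & (lo.fraction > 0.49)
        assert core.any()
        assert np.allclose(hi.fraction[core] + lo.fraction[core], 1.0,
                           atol=1e-9)

    def test_masks_overlap_only_in_designed_regions(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        hi, lo = gt.bundles["cross_high"], gt.bundles["cross_low"]
        overlap = np.argwhere(hi.mask & lo.mask)
        # crossing designed at world (0, 0) with tube radius 2.5
        xy = overlap[:, :2] * spec.voxel_mm + spec.affine[:2, 3]
        assert np.all(np.abs(xy) <= 2 * 2.5 + spec.voxel_mm)
        # the bend shares no voxel with any other bundle
        others = [b.mask for n, b in gt.bundles.items() if n != "bend"]
        assert not np.any(gt.bundles["bend"].mask & np.logical_or.reduce(others))

    def test_bend_turns_at_least_80_degrees(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        pts = gt.bundles["bend"].centerline_points
        t0 = pts[1] - pts[0]
        t1 = pts[-1] - pts[-2]
        cos = (t0 @ t1) / np.linalg.norm(t0) / np.linalg.norm(t1)
        assert np.degrees(np.arccos(cos)) >= 80

    def test_split_has_three_branches_sharing_a_trunk(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        trunk = gt.bundles["split_1"].mask & gt.bundles["split_2"].mask \
            & gt.bundles["split_3"].mask
        assert trunk.any()
        ends = [gt.bundles[f"split_{i}"].centerline_points[-1]
                for i in (1, 2, 3)]
        assert len({tuple(np.round(e)) for e in ends}) == 3

    def test_crossing_bundles_have_distinct_fa(self, std_noiseless):
        spec, gt, dwi, eigs, maps = std_noiseless
        hi, lo = gt.bundles["cross_high"], gt.bundles["cross_low"]
        hi_only = hi.mask & (hi.fraction > 0.99) & ~lo.mask
        lo_only = lo.mask & (lo.fraction > 0.99) & ~hi.mask
        fa_hi = maps.fa[hi_only].mean()
        fa_lo = maps.fa[lo_only].mean()
        expected_hi = tensor.fractional_anisotropy(
            np.array([1.43, 0.29, 0.29]))
        assert fa_hi == pytest.approx(expected_hi, abs=1e-3)
        assert fa_hi - fa_lo > 0.2

    def test_volume_fractions_conserved(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        total = sum(b.fraction for b in gt.bundles.values())
        assert total.max() <= 1.0 + 1e-9
        assert np.all(gt.background_fraction() >= -1e-9)

    def test_tangents_unit_norm(self, std_noiseless):
        spec, gt, *_ = std_noiseless
        for b in gt.bundles.values():
            t = b.tangent[b.mask]
            assert np.allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-9)


class TestForwardModel:
    def test_single_bundle_closed_form(self):
        """S/S0 = exp(-b ad) = exp(-1.16) for a gradient exactly along the
        bundle axis, noiseless, in a fully intra-bundle voxel."""
        spec, gt = tb.make_single_bundle_phantom(snr=None, ad=1.16, rd=0.29)
        dirs = np.vstack([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                          np.array([1, 1, 0]) / np.sqrt(2),
                          np.array([1, 0, 1]) / np.sqrt(2),
                          np.array([0, 1, 1]) / np.sqrt(2)])
        from tractbench.dwi import GradientTable
        gtab = GradientTable(np.r_[0.0, [1000.0] * 6],
                             np.vstack([np.zeros(3), dirs]))
        dwi = simulate_dwi(spec, gt, gtab)
        bt = gt.bundles["bundle"]
        i, j, k = np.argwhere(bt.fraction == 1.0)[0]
        assert dwi.signal[i, j, k, 1] == pytest.approx(np.exp(-1.16),
                                                       rel=1e-9)
        # perpendicular gradient sees only the radial diffusivity
        assert dwi.signal[i, j, k, 2] == pytest.approx(np.exp(-0.29),
                                                       rel=1e-9)

    def test_b0_equals_s0(self, std_noiseless):
        spec, gt, dwi, *_ = std_noiseless
        assert np.allclose(dwi.signal[..., dwi.gradients.b0_mask], 1.0,
                           atol=1e-12)

    def test_rician_moments(self, rng):
        """Sample mean of the noisy signal matches the analytic Rician mean
        (Monte-Carlo vs closed-form first moment) within 3 SE."""
        from scipy.special import ive
        spec, gt = tb.make_single_bundle_phantom(snr=20.0)
        gtab = make_gradient_table()
        draws = np.array([
            simulate_dwi(spec, gt, gtab, rng_seed=s).signal[0, 0, 0, 1]
            for s in range(500)
        ])
        spec0, gt0 = tb.make_single_bundle_phantom(snr=None)
        a = simulate_dwi(spec0, gt0, gtab).signal[0, 0, 0, 1]
        sigma = 1.0 / 20.0
        x = -a ** 2 / (2 * sigma ** 2)
        # E[S] for Rician: sigma sqrt(pi/2) L_{1/2}(x); the exp(x/2) of the
        # Laguerre identity cancels against the scaling of ive
        l_half = (1 - x) * ive(0, -x / 2) - x * ive(1, -x / 2)
        mean_analytic = sigma * np.sqrt(np.pi / 2) * l_half
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - mean_analytic) < 3 * se

    def test_determinism(self):
        spec, gt = tb.make_standard_phantom(snr=20.0, rng_seed=11)
        a = simulate_dwi(spec, gt)
        b = simulate_dwi(spec, gt)
        assert np.array_equal(a.signal, b.signal)

    def test_noise_free_roundtrip_recovers_targets(self, std_noiseless):
        """simulate -> fit -> metrics recovers (ad, rd) within 1e-3 in
        single-bundle voxels (end-to-end oracle)."""
        spec, gt, dwi, eigs, maps = std_noiseless
        lo = gt.bundles["cross_low"]
        pure = lo.mask & (lo.fraction > 0.999) & \
            ~gt.bundles["cross_high"].mask
        assert pure.any()
        assert np.allclose(maps.ad[pure], 1.05, atol=1e-3)
        assert np.allclose(maps.rd[pure], 0.45, atol=1e-3)


class TestLesions:
    def test_identity_lesion_is_noop(self):
        spec, gt = tb.make_single_bundle_phantom(snr=None)
        les = LesionSpec(center=(0, 0, 9), radius_mm=6.0)
        spec2, gt2 = tb.apply_lesion(spec, gt, les)
        d1 = simulate_dwi(spec, gt)
        d2 = simulate_dwi(spec2, gt2)
        assert np.array_equal(d1.signal, d2.signal)

    def test_lesion_reaches_designed_diffusivities(self):
        """Multipliers chosen for lesion-center (AD, RD) = (0.64, 0.21)
        — the severe-compression regime — are recovered by the fit at
        SNR 20 within 0.05."""
        spec, gt = tb.make_single_bundle_phantom(snr=20.0, rng_seed=3,
                                                 ad=1.08, rd=0.46)
        z = gt.bundles["bundle"].centerline_points[0][2]
        les = LesionSpec(center=(0.0, 0.0, z), radius_mm=8.0,
                         ad_multiplier=0.64 / 1.08,
                         rd_multiplier=0.21 / 0.46)
        spec2, gt2 = tb.apply_lesion(spec, gt, les)
        dwi = simulate_dwi(spec2, gt2)
        eigs, maps = fit_pipeline(dwi)
        bt = gt2.bundles["bundle"]
        centers = np.argwhere(bt.mask) * spec.voxel_mm + spec.affine[:3, 3]
        near = np.linalg.norm(centers - les.center, axis=1) < 2.0
        sel = np.argwhere(bt.mask)[near]
        ad = maps.ad[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
        rd = maps.rd[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
        assert ad == pytest.approx(0.64, abs=0.05)
        assert rd == pytest.approx(0.21, abs=0.05)

    def test_displacement_shifts_midline(self):
        spec, gt = tb.make_mirrored_phantom(snr=None)
        les = LesionSpec(center=(16.0, 0.0, 28.0), radius_mm=10.0,
                         displacement_mm=(-6.0, 0.0, 0.0))
        spec2, gt2 = tb.apply_lesion(spec, gt, les)
        pts = gt2.bundles["right"].centerline_points
        mid = pts[np.argmin(np.abs(pts[:, 2] - 28.0))]
        assert mid[0] == pytest.approx(16.0 - 6.0, abs=0.3)
        far = pts[np.argmax(np.abs(pts[:, 2] - 28.0))]
        assert far[0] == pytest.approx(16.0, abs=0.3)   # falloff

    def test_deviation_monotone_with_displacement(self):
        """Recovered |d_h - d_p| grows monotonically with the designed
        displacement (measured on the ground-truth masks at the lesion
        level)."""
        from tractbench import analysis
        gaps = []
        for disp in (2.0, 4.0, 6.0, 8.0):
            spec, gt = tb.make_mirrored_phantom(snr=None)
            les = LesionSpec(center=(16.0, 0.0, 28.0), radius_mm=10.0,
                             displacement_mm=(-disp, 0.0, 0.0))
            spec2, gt2 = tb.apply_lesion(spec, gt, les)
            rp = analysis.TractROI(gt2.bundles["right"].mask, spec.affine)
            rh = analysis.TractROI(gt2.bundles["left"].mask, spec.affine)
            d_h, d_p = analysis.midline_distances(rp, rh, 28.0)
            gaps.append(abs(d_h - d_p))
            assert analysis.deviation_index(d_h, d_p) > 0
        assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            LesionSpec(center=(0, 0, 0), radius_mm=-1.0)
        with pytest.raises(ValueError):
            LesionSpec(center=(0, 0, 0), radius_mm=1.0, ad_multiplier=0.0)
        spec, gt = tb.make_single_bundle_phantom(snr=None)
        with pytest.raises(ValueError):
            tb.apply_lesion(spec, gt, LesionSpec(center=(0, 0, 9),
                                                 radius_mm=500.0))


def test_spec_contracts():
    with pytest.raises(ValueError):
        PhantomSpec(shape=(4, 4, 4), voxel_mm=-1.0, bundles=())
    with pytest.raises(ValueError):
        PhantomSpec(shape=(4, 4, 4), voxel_mm=2.0, bundles=(), snr=-5.0)
    with pytest.raises(ValueError):
        BundleGeometry("x", [(0, 0, 0)], 2.0, 1.0, 0.5, ("a", "b"))
    with pytest.raises(ValueError):
        BundleGeometry("x", [(0, 0, 0), (1, 0, 0)], 2.0, 0.4, 0.5, ("a", "b"))
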