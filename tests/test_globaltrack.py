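"""Global tracking sampler tests: kernel, energy, Metropolis, chains."""

import itertools

import numpy as np
import pytest

import tractbench as tb
from tractbench import globaltrack as gtk
from tractbench.dwi import make_gradient_table
from tractbench.globaltrack import (GTParams, SegmentConfiguration, anneal,
                                    extract_fibres, metropolis_step,
                                    predicted_signal)


GTAB = make_gradient_table()


def empty_config(params=None, shape=(6, 6, 6), measured=None):
    p = params or GTParams(segment_weight=0.1)
    mask = np.ones(shape, bool)
    affine = np.eye(4)
    affine[:3, :3] *= 2.0
    return SegmentConfiguration(shape, affine, GTAB, mask, p, measured)


class TestPredictedSignal:
    def test_empty_configuration_is_zero(self):
        cfg = empty_config()
        assert np.all(predicted_signal(cfg, GTAB) == 0)

    def test_perpendicular_gradient_no_attenuation(self):
        """For g perpendicular to the axis the deposit is the full weight
        w * overlap (here overlap = 1: all quadrature points in one voxel)."""
        cfg = empty_config()
        center = np.array([4.0, 4.0, 4.0])    # a voxel center (2 mm voxels)
        cfg.insert_segment(center, [1.0, 0.0, 0.0])
        pred = predicted_signal(cfg, GTAB)
        perp = np.argmax(np.abs(GTAB.bvecs[:, 2]) * (GTAB.bvals > 0))
        gz = GTAB.bvecs[perp]
        vox = tuple((center / 2).astype(int))
        expected = 0.1 * np.exp(-1.0 * gz[0] ** 2)   # (g.n)^2 = gx^2
        assert pred[vox + (perp,)] == pytest.approx(expected, rel=1e-9)
        # b0 entry: unattenuated deposit
        assert pred[vox + (0,)] == pytest.approx(0.1, rel=1e-12)

    def test_linearity_of_30_aligned_segments(self):
        cfg = empty_config()
        center = np.array([4.0, 4.0, 4.0])
        for _ in range(30):
            cfg.insert_segment(center, [1.0, 0.0, 0.0])
        pred = predicted_signal(cfg, GTAB)
        single = (0.1 / 3.0) * np.exp(
            -GTAB.bvals * 1e-3 * GTAB.bvecs[:, 0] ** 2)
        vox = tuple((center / 2).astype(int))
        assert np.allclose(pred[vox], 30 * 3 * single, atol=1e-9)


class TestEnergy:
    def test_empty_config_energy(self):
        rngm = np.random.default_rng(0)
        m = rngm.random((6, 6, 6, 61))
        cfg = empty_config(measured=m)
        e_data, e_bond = gtk.energy(cfg)
        assert e_data == pytest.approx((m ** 2).sum())
        assert e_bond == 0.0

    def test_bonding_collinear_lowers_energy(self):
        cfg = empty_config()
        a = cfg.insert_segment([4.0, 4.0, 4.0], [1, 0, 0])
        b = cfg.insert_segment([7.2, 4.0, 4.0], [1, 0, 0])
        e0 = sum(gtk.energy(cfg))
        cfg.create_bond(a, 1, b, 0)
        e1 = sum(gtk.energy(cfg))
        assert e1 < e0

    def test_orthogonal_bond_raises_energy(self):
        """At 90 degrees the curvature penalty exceeds the bond reward."""
        cfg = empty_config()
        a = cfg.insert_segment([4.0, 4.0, 4.0], [1, 0, 0])
        b = cfg.insert_segment([5.5, 5.5, 4.0], [0, 1, 0])
        e0 = sum(gtk.energy(cfg))
        cfg.create_bond(a, 1, b, 0)
        assert sum(gtk.energy(cfg)) > e0

    def test_incremental_bookkeeping_matches_scratch(self, single_bundle20):
        """Energy audit: incremental (E_data, E_bond) equal a from-scratch
        recomputation during annealing."""
        spec, gt, dwi, *_ = single_bundle20
        params = GTParams(n_iterations=30_000, rng_seed=4)
        cfg = anneal(dwi, gt.bundle_union(), params, audit_interval=10_000)
        ed, eb = cfg.energies_from_scratch()
        assert cfg.E_data == pytest.approx(ed, abs=1e-6)
        assert cfg.E_bond == pytest.approx(eb, abs=1e-6)


class TestMetropolis:
    def test_downhill_always_accepted_uphill_at_high_t(self):
        """At T -> infinity the empirical acceptance rate approaches 1."""
        rng = np.random.default_rng(0)
        m = 0.3 * np.ones((6, 6, 6, 61))
        p = GTParams(segment_weight=0.1)
        cfg = empty_config(params=p, measured=m)
        acc = sum(metropolis_step(cfg, p, 1e9, rng) for _ in range(10_000))
        # death/bond proposals on an empty config are no-ops, so compare
        # against the number of *possible* proposals
        assert acc / cfg.n_proposed > 0.45          # births+moves ~ 55%
        assert cfg.n_segments() > 0

    def test_detailed_balance_on_toy_bond_space(self):
        """Three collinear segments, bond-flip proposals only: the empirical
        occupancy of the four bond states matches the Boltzmann distribution
        at fixed temperature."""
        T = 0.05
        p = GTParams(segment_weight=0.0, proposal_probs=(0, 0, 0, 1.0),
                     spring=0.05, curvature_penalty=0.15, bond_reward=0.1)
        cfg = empty_config(params=p, shape=(8, 8, 8))
        # centers 3.4 mm apart: adjacent endpoints 0.4 mm, within bond radius
        s0 = cfg.insert_segment([2.0, 4.0, 4.0], [1, 0, 0])
        s1 = cfg.insert_segment([5.4, 4.0, 4.0], [1, 0, 0])
        s2 = cfg.insert_segment([8.8, 4.0, 4.0], [1, 0, 0])
        e01 = cfg.bond_energy(s0, 1, s1, 0)
        e12 = cfg.bond_energy(s1, 1, s2, 0)
        states = {}
        weights = {}
        for b01, b12 in itertools.product([0, 1], repeat=2):
            weights[(b01, b12)] = np.exp(-(b01 * e01 + b12 * e12) / T)
        z = sum(weights.values())
        rng = np.random.default_rng(99)
        counts = {k: 0 for k in weights}
        n_steps = 200_000
        for step in range(n_steps):
            metropolis_step(cfg, p, T, rng)
            if step % 10 == 0:
                state = (int(cfg.bonds[s0][1] is not None),
                         int(cfg.bonds[s1][1] is not None))
                counts[state] += 1
        n_samp = sum(counts.values())
        for k, w in weights.items():
            expect = w / z
            # binomial SE on thinned samples (thinning ~decorrelates)
            se = np.sqrt(expect * (1 - expect) / n_samp)
            assert counts[k] / n_samp == pytest.approx(expect, abs=4 * se)

    def test_temperature_contract(self):
        cfg = empty_config()
        with pytest.raises(ValueError):
            metropolis_step(cfg, cfg.params, 0.0, np.random.default_rng(0))


class TestAnneal:
    def test_zero_iterations_empty(self, single_bundle20):
        spec, gt, dwi, *_ = single_bundle20
        cfg = anneal(dwi, gt.bundle_union(), GTParams(n_iterations=0))
        assert cfg.n_segments() == 0

    def test_energy_decreases(self, single_bundle20):
        """Median E_data over the last decile of the schedule is below the
        median over the first decile."""
        spec, gt, dwi, *_ = single_bundle20
        params = GTParams(n_iterations=100_000, rng_seed=5)
        cfg = anneal(dwi, gt.bundle_union(), params)
        ed = [e[2] for e in cfg.energy_history]
        k = max(1, len(ed) // 10)
        assert np.median(ed[-k:]) < np.median(ed[:k])

    def test_seeded_determinism(self, single_bundle20):
        spec, gt, dwi, *_ = single_bundle20
        params = GTParams(n_iterations=20_000, rng_seed=6)
        a = anneal(dwi, gt.bundle_union(), params)
        b = anneal(dwi, gt.bundle_union(), params)
        ia, ca, oa = a.segment_arrays()
        ib, cb, ob = b.segment_arrays()
        assert ia == ib
        assert np.array_equal(ca, cb) and np.array_equal(oa, ob)
        assert a.bonds == b.bonds

    def test_segments_align_with_bundle(self, single_bundle20):
        """After annealing, most segments lie in the bundle and most of
        those are aligned with the local tangent."""
        spec, gt, dwi, *_ = single_bundle20
        params = GTParams(n_iterations=150_000, rng_seed=7)
        cfg = anneal(dwi, gt.bundle_union(), params)
        idx, c, o = cfg.segment_arrays()
        bt = gt.bundles["bundle"]
        inv = np.linalg.inv(spec.affine)
        vox = np.round(c @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(spec.shape)), axis=1)
        inside = bt.mask[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
        assert inside.mean() >= 0.9
        tang = bt.tangent[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
        align = np.abs(np.einsum("ij,ij->i", o[ok], tang))
        assert (align[inside] > 0.9).mean() >= 0.9

    def test_weight_acts_like_fa_threshold(self):
        """Doubling the segment weight does not increase the number of final
        segments in low-anisotropy (FA < 0.1) territory."""
        spec, gt = tb.make_single_bundle_phantom(snr=20.0, rng_seed=8)
        dwi = tb.simulate_dwi(spec, gt)
        mask = np.ones(spec.shape, bool)       # births allowed everywhere
        w = gtk.default_segment_weight(dwi, gt.bundle_union())
        counts = []
        for factor in (1.0, 2.0):
            params = GTParams(segment_weight=factor * w,
                              n_iterations=60_000, rng_seed=9)
            cfg = anneal(dwi, mask, params)
            idx, c, o = cfg.segment_arrays()
            inv = np.linalg.inv(spec.affine)
            vox = np.round(c @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((vox >= 0) & (vox < np.array(spec.shape)), axis=1)
            outside = ~gt.bundle_union()[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
            counts.append(int(outside.sum()))
        assert counts[1] <= counts[0]


class TestExtractFibres:
    def test_five_segments_in_a_line(self):
        cfg = empty_config(shape=(12, 12, 12))
        idx = [cfg.insert_segment([2.0 + 3.2 * i, 4.0, 4.0], [1, 0, 0])
               for i in range(5)]
        for a, b in zip(idx[:-1], idx[1:]):
            cfg.create_bond(a, 1, b, 0)
        out = extract_fibres(cfg, min_chain_segments=2)
        assert len(out) == 1
        line = out.streamlines[0]
        assert len(line) == 6
        assert np.allclose(np.diff(line[:, 0]) > 0, True) or \
            np.allclose(np.diff(line[:, 0]) < 0, True)

    def test_no_bonds_no_fibres(self):
        cfg = empty_config()
        cfg.insert_segment([4.0, 4.0, 4.0], [1, 0, 0])
        cfg.insert_segment([8.0, 4.0, 4.0], [1, 0, 0])
        assert len(extract_fibres(cfg, min_chain_segments=2)) == 0

    def test_bond_symmetry_enforced(self):
        cfg = empty_config()
        a = cfg.insert_segment([4.0, 4.0, 4.0], [1, 0, 0])
        b = cfg.insert_segment([7.2, 4.0, 4.0], [1, 0, 0])
        cfg.create_bond(a, 1, b, 0)
        cfg.bonds[b][0] = None                 # corrupt on purpose
        with pytest.raises(ValueError):
            extract_fibres(cfg, min_chain_segments=2)


def test_params_contracts():
    with pytest.raises(ValueError):
        GTParams(t_start=0.001, t_stop=0.1)
    with pytest.raises(ValueError):
        GTParams(proposal_probs=(0.5, 0.5, 0.5, 0.5))
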