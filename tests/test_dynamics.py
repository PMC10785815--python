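"""Brownian integrator: determinism, diffusion, equilibrium sampling."""

import numpy as np
import pytest
from scipy import stats

from silicabrush.builder import GeometryParams, build_core
from silicabrush.dynamics import (
    InstabilityError,
    IntegratorParams,
    SimulationState,
    run,
    step,
    total_forces,
)
from silicabrush.forcefield import ForceFieldParams
from silicabrush.topology import Boundary, BoxSpec, CGTopology, Species


def free_gas(n=1000, edge=200.0, seed=0):
    topo = CGTopology()
    rng = np.random.default_rng(seed)
    topo.add_beads(Species.PRECURSOR, rng.random((n, 3)) * edge, 0.0, 0.5)
    box = BoxSpec([edge] * 3, [Boundary.PERIODIC] * 3)
    ff = ForceFieldParams(attraction_epsilon=0.0, wca_epsilon=0.0)
    return topo, box, ff


class TestStep:
    def test_zero_steps_noop(self, small_system):
        box = small_system.box
        state = SimulationState(small_system.topo.position.copy(), 0.0, box)
        out = step(state, small_system.topo, ForceFieldParams(),
                   IntegratorParams(seed=1), n_steps=0)
        assert np.array_equal(out.positions, state.positions)

    def test_fixed_beads_bit_identical(self, small_system):
        topo = small_system.topo
        ip = IntegratorParams(n_steps=2000, frame_stride=1000, seed=8)
        traj = run(topo, small_system.box, ForceFieldParams(), ip)
        core = topo.mask(Species.CORE)
        for f in range(traj.n_frames):
            assert np.array_equal(traj.frames[f][core], traj.frames[0][core])

    def test_instability_error_when_dt_too_large(self, small_system):
        ip = IntegratorParams(dt=5.0, n_steps=200, frame_stride=100, seed=0,
                              relax_steps=0, max_force_displacement=np.inf)
        with pytest.raises(InstabilityError):
            run(small_system.topo, small_system.box, ForceFieldParams(), ip)


class TestRun:
    def test_stride_equals_steps_gives_two_frames(self, small_system):
        ip = IntegratorParams(n_steps=500, frame_stride=500, seed=2)
        traj = run(small_system.topo, small_system.box, ForceFieldParams(), ip)
        assert traj.n_frames == 2

    def test_same_seed_identical_trajectories(self, small_system):
        ip = IntegratorParams(n_steps=1500, frame_stride=500, seed=42)
        ff = ForceFieldParams()
        t1 = run(small_system.topo, small_system.box, ff, ip)
        t2 = run(small_system.topo, small_system.box, ff, ip)
        assert np.array_equal(t1.frames, t2.frames)

    def test_different_seed_differs(self, small_system):
        ff = ForceFieldParams()
        t1 = run(small_system.topo, small_system.box, ff,
                 IntegratorParams(n_steps=500, frame_stride=500, seed=1))
        t2 = run(small_system.topo, small_system.box, ff,
                 IntegratorParams(n_steps=500, frame_stride=500, seed=2))
        assert not np.array_equal(t1.frames[-1], t2.frames[-1])

    def test_precursor_count_conserved(self, small_system):
        """Reflecting walls + periodic axis never lose precursors."""
        ip = IntegratorParams(n_steps=3000, frame_stride=1000, seed=5)
        traj = run(small_system.topo, small_system.box, ForceFieldParams(), ip)
        for f in range(traj.n_frames):
            assert small_system.box.contains(traj.frames[f])

    def test_metadata_provenance(self, small_system):
        ip = IntegratorParams(n_steps=200, frame_stride=100, seed=7)
        traj = run(small_system.topo, small_system.box, ForceFieldParams(), ip)
        assert traj.metadata["seed"] == 7
        assert "params_hash" in traj.metadata
        assert traj.metadata["equilibration_fraction"] == 0.5


class TestEinsteinRelation:
    def test_free_diffusion_msd_slope(self):
        """MSD grows as 6 D t with D = k_BT/gamma, within 5%."""
        topo, box, ff = free_gas(1000)
        ip = IntegratorParams(dt=0.005, n_steps=10_000, frame_stride=500,
                              seed=3, relax_steps=0)
        traj = run(topo, box, ff, ip)
        gamma = ip.gamma_per_radius * 0.5
        d_expected = 1.0 / gamma
        slopes = []
        L = box.lengths[0]
        for f in range(1, traj.n_frames):
            d = traj.frames[f] - traj.frames[f - 1]
            d -= L * np.round(d / L)
            dt_f = traj.times[f] - traj.times[f - 1]
            slopes.append(np.mean(np.sum(d ** 2, axis=1)) / dt_f)
        assert np.mean(slopes) == pytest.approx(6.0 * d_expected, rel=0.05)


class TestBoltzmannSampling:
    def test_radial_distribution_single_charge(self):
        """Probes around one fixed charge sample r^2 exp(-U(r)).

        Detailed-balance smoke test: ~10^6 position samples from dilute
        probes (mutual interactions ~5e-3 k_BT, far below resolution); the
        chi-square uses batch-means variances, since successive samples of a
        diffusing particle are autocorrelated.
        """
        topo = CGTopology()
        edge = 10.0
        centre = np.array([edge / 2] * 3)
        topo.add_beads(Species.CORE, [centre], -2.0, 0.8, fixed=True)
        rng = np.random.default_rng(5)
        pts = rng.random((24, 3)) * (edge - 2.0) + 1.0
        topo.add_beads(Species.PRECURSOR, pts, 1.0, 0.5)
        box = BoxSpec([edge] * 3, [Boundary.REFLECTING] * 3)
        ff = ForceFieldParams(debye_length=1.0, attraction_epsilon=0.0)
        stride = 25
        ip = IntegratorParams(dt=0.001, n_steps=1_600_000, frame_stride=stride,
                              seed=17, relax_steps=200)
        traj = run(topo, box, ff, ip)
        burn = traj.n_frames // 6
        r = np.linalg.norm(traj.frames[burn:, 1:, :] - centre, axis=2)  # (F, 24)
        lo, hi, nbins = 1.6, 3.6, 12
        edges = np.linspace(lo, hi, nbins + 1)
        # expected bin probabilities: r^2 exp(-U(r)) by fine quadrature
        rr = np.linspace(lo, hi, 3201)
        u = ff.bjerrum_length * (-2.0) * np.exp(-rr / ff.debye_length) / rr
        w = rr ** 2 * np.exp(-u)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, rr, cdf))
        # batch-means: per-batch bin proportions, variance across batches
        n_batches = 16
        splits = np.array_split(np.arange(len(r)), n_batches)
        props = []
        for idx in splits:
            sel = r[idx].ravel()
            sel = sel[(sel >= lo) & (sel < hi)]
            h, _ = np.histogram(sel, bins=edges)
            props.append(h / h.sum())
        props = np.asarray(props)
        assert r.shape[0] * r.shape[1] > 1_000_000  # raw sample count
        mean = props.mean(axis=0)
        se = props.std(axis=0, ddof=1) / np.sqrt(n_batches)
        chi2 = (((mean - probs) / se) ** 2).sum()
        p = 1.0 - stats.chi2.cdf(chi2, df=nbins - 1)
        assert p > 0.01

    def test_no_core_penetration(self, small_system):
        """No mobile bead inside 0.8 x contact of a CORE bead in any frame."""
        from scipy.spatial import cKDTree

        topo = small_system.topo
        ip = IntegratorParams(n_steps=5000, frame_stride=500, seed=9)
        traj = run(topo, small_system.box, ForceFieldParams(), ip)
        core = topo.mask(Species.CORE)
        mobile = ~topo.fixed
        L = small_system.box.lengths[2]
        min_contact = 0.8 * (1.0 + topo.radius[mobile].min())
        for f in range(traj.n_frames):
            cpos = traj.frames[f][core]
            images = np.vstack([cpos + [0, 0, dz] for dz in (-L, 0.0, L)])
            d, _ = cKDTree(images).query(traj.frames[f][mobile], k=1)
            assert d.min() > min_contact


class TestChainStiffness:
    def test_ds_persistence_length_matches_parameter(self):
        """Free double-strand-parameter chains sample the configured
        worm-like-chain stiffness (within 20%)."""
        from silicabrush.builder import DS_BRUSH
        from silicabrush.wlc import contour_from_xyz, estimate_lp

        topo = CGTopology()
        edge = 300.0
        box = BoxSpec([edge] * 3, [Boundary.PERIODIC] * 3)
        n_chains, n_beads = 24, 30
        rng = np.random.default_rng(0)
        for c in range(n_chains):
            start = rng.random(3) * edge
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            pts = start + np.arange(n_beads)[:, None] * DS_BRUSH.bond_length * axis
            idx = topo.add_beads(Species.DS_BEAD, pts, 0.0, DS_BRUSH.bead_radius)
            topo.add_bonds(np.column_stack([idx[:-1], idx[1:]]),
                           DS_BRUSH.bond_length, DS_BRUSH.bond_k)
            topo.add_angles(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]),
                            np.pi, DS_BRUSH.bending_kappa)
        ff = ForceFieldParams(attraction_epsilon=0.0, wca_epsilon=0.0)
        ip = IntegratorParams(dt=0.001, n_steps=30_000, frame_stride=1500, seed=4)
        traj = run(topo, box, ff, ip)
        target = DS_BRUSH.bending_kappa * DS_BRUSH.bond_length  # kappa*b in k_BT
        contours = []
        for f in traj.analysis_window():
            frame = traj.frames[f]
            # unwrap each chain before tracing (chains can cross the box)
            for c in range(n_chains):
                pts = frame[c * n_beads:(c + 1) * n_beads].copy()
                d = np.diff(pts, axis=0)
                d -= edge * np.round(d / edge)
                pts = np.vstack([pts[0], pts[0] + np.cumsum(d, axis=0)])
                contours.append(contour_from_xyz(pts, DS_BRUSH.bond_length))
        # chord resampling of bead-level traces adds a positive offset to the
        # log correlation, so the fit carries a free intercept here
        fit = estimate_lp(contours, convention="3D", n_boot=0, fit_intercept=True)
        assert fit.persistence_length == pytest.approx(target, rel=0.20)
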