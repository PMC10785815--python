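"""Condensation, residence, charge-profile and probe-scan analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from silicabrush.analysis import (
    RegionalCondensationResult,
    assign_regions,
    condensed_counts,
    condensation_timeseries,
    electrostatic_scan,
    enhancement,
    mg_sweep,
    radial_charge_profile,
    residence_times,
)
from silicabrush.builder import GeometryParams, build_system
from silicabrush.dynamics import Trajectory
from silicabrush.forcefield import ForceFieldParams, debye_length
from silicabrush.layout import parse_layout
from silicabrush.topology import Boundary, BoxSpec, CGTopology, Species

BUNDLE = 27 * 14.28


class TestRegions:
    def test_brush_fraction_10_27(self):
        rmap = assign_regions(parse_layout("6HB-5*/17/5*-DS"), BUNDLE)
        assert rmap.length("BRUSH") == pytest.approx(BUNDLE * 10 / 27)
        assert rmap.length("BARE") == pytest.approx(BUNDLE * 17 / 27)
        assert rmap.labels == ("BRUSH", "BARE", "BRUSH")

    def test_bare_and_full_layouts(self):
        assert assign_regions(parse_layout("6HB"), BUNDLE).labels == ("BARE",)
        assert assign_regions(parse_layout("6HB-27*-SS"), BUNDLE).labels == ("BRUSH",)

    def test_half_open_boundary(self):
        rmap = assign_regions(parse_layout("6HB-1*/1/1*-DS", n_domains=3), 30.0)
        assert rmap.label_of(10.0) == "BARE"   # [10, 20) is the middle segment
        assert rmap.label_of(20.0) == "BRUSH"
        assert rmap.label_of(9.999) == "BRUSH"


def _frame_with_precursors(offsets):
    """3-domain bundle with precursors at given (x-offset, z) from the axis."""
    sys_ = build_system(parse_layout("6HB-1*/1/1*-DS", n_domains=3),
                        geometry=GeometryParams.for_domains(3),
                        brush_contour=6.0, n_precursors=0, seed=0, box_xy=30.0)
    topo = sys_.topo
    cx, cy = sys_.box.center()[:2]
    pts = [[cx + dx, cy, z] for dx, z in offsets]
    topo.add_beads(Species.PRECURSOR, pts, 1.0, 0.5)
    return sys_, topo


class TestCondensedCounts:
    def test_all_far_gives_zero(self):
        sys_, topo = _frame_with_precursors([(12.0, 5.0), (13.0, 20.0)])
        rmap = assign_regions(sys_.spec, sys_.geometry.bundle_length)
        assert condensed_counts(topo.position, topo, rmap, sys_.box) == (0, 0)

    def test_bruteforce_agreement(self):
        """Hand-placed precursors match a direct distance computation."""
        offsets = [(3.2, 5.0), (4.4, 21.0), (3.4, 35.0), (9.0, 21.0), (3.1, 21.4)]
        sys_, topo = _frame_with_precursors(offsets)
        rmap = assign_regions(sys_.spec, sys_.geometry.bundle_length)
        got = condensed_counts(topo.position, topo, rmap, sys_.box, r_condense=1.5)
        core = topo.mask(Species.CORE)
        pre = topo.mask(Species.PRECURSOR)
        L = sys_.box.lengths[2]
        nb = nb2 = 0
        for p in topo.position[pre]:
            d = topo.position[core] - p
            d[:, 2] -= L * np.round(d[:, 2] / L)
            dist = np.sqrt((d ** 2).sum(1))
            if dist.min() <= 1.5:
                z = topo.position[core][np.argmin(dist), 2]
                if rmap.label_of(z) == "BRUSH":
                    nb += 1
                else:
                    nb2 += 1
        assert got == (nb, nb2)
        assert got[0] + got[1] == 3  # three of five placed within reach

    def test_r_condense_positive(self):
        sys_, topo = _frame_with_precursors([(3.2, 5.0)])
        rmap = assign_regions(sys_.spec, sys_.geometry.bundle_length)
        with pytest.raises(ValueError):
            condensed_counts(topo.position, topo, rmap, sys_.box, r_condense=0.0)


class TestEnhancementStatistic:
    def _result(self, counts_brush, counts_bare, lb=10.0, l0=20.0):
        rmap = assign_regions(parse_layout("6HB-1*/2-DS", n_domains=3), 30.0)
        t = np.arange(len(counts_brush), dtype=float)
        return RegionalCondensationResult(
            t, np.asarray(counts_brush, float), np.asarray(counts_bare, float), rmap)

    def test_per_length_density_normalisation(self):
        # brush region 10 nm, bare 20 nm: equal densities => 0% enhancement
        res = self._result([4, 4, 4, 4], [8, 8, 8, 8])
        assert res.enhancement_percent == pytest.approx(0.0)

    def test_window_excludes_first_half(self):
        res = self._result([0, 0, 4, 4], [8, 8, 8, 8])
        # only the last two frames count
        assert res.rho_brush == pytest.approx(0.4)

    def test_seed_statistics_pooled_ratio_and_jackknife(self):
        results = [self._result([4, 4], [4, 4]), self._result([6, 6], [4, 4]),
                   self._result([5, 5], [4, 4])]
        mean, se, vals = enhancement(results)
        # pooled densities: mean rho_brush 0.5, mean rho_bare 0.2 -> 150%
        assert mean == pytest.approx(150.0)
        assert vals == pytest.approx([100.0, 200.0, 150.0])
        # leave-one-out pooled estimates are 175, 125, 150
        loo = np.array([175.0, 125.0, 150.0])
        expect_se = math.sqrt(2 / 3 * ((loo - loo.mean()) ** 2).sum())
        assert se == pytest.approx(expect_se)

    def test_identical_seeds_zero_se(self):
        results = [self._result([4, 4], [4, 4])] * 4
        mean, se, _ = enhancement(results)
        assert mean == pytest.approx(100.0)
        assert se == pytest.approx(0.0, abs=1e-12)


def _synthetic_traj(topo, box, near_pattern, brush_pos, far_pos):
    """Trajectory whose single precursor follows near/far pattern vs a brush bead."""
    frames = []
    pre = int(np.flatnonzero(topo.mask(Species.PRECURSOR))[0])
    for near in near_pattern:
        f = topo.position.copy()
        f[pre] = brush_pos + [0.8, 0, 0] if near else far_pos
        frames.append(f)
    times = np.arange(len(frames), dtype=float)
    return Trajectory(np.asarray(frames), times, box, {})


class TestResidence:
    def _setup(self):
        topo = CGTopology()
        box = BoxSpec([20, 20, 20])
        topo.add_beads(Species.DS_BEAD, [[10, 10, 10]], -1.5, 0.5)
        topo.add_beads(Species.PRECURSOR, [[18, 18, 18]], 1.0, 0.5)
        return topo, box, np.array([10.0, 10.0, 10.0]), np.array([18.0, 18.0, 18.0])

    def test_never_near_no_events(self):
        topo, box, bpos, fpos = self._setup()
        traj = _synthetic_traj(topo, box, [False] * 6, bpos, fpos)
        events, means = residence_times(traj, topo, r_near=1.2)
        assert events == []

    def test_always_near_single_full_event(self):
        topo, box, bpos, fpos = self._setup()
        traj = _synthetic_traj(topo, box, [True] * 6, bpos, fpos)
        events, means = residence_times(traj, topo, r_near=1.2)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(6.0)  # 5 intervals + entry frame
        assert means["DS"] == pytest.approx(6.0)

    def test_grace_merges_short_excursion(self):
        """A 2-frame excursion with grace=3 merges into one event; with
        grace=0 it splits into two (hand-computed durations)."""
        topo, box, bpos, fpos = self._setup()
        pattern = [True, True, False, False, True, True]
        traj = _synthetic_traj(topo, box, pattern, bpos, fpos)
        merged, _ = residence_times(traj, topo, r_near=1.2, grace=3)
        assert len(merged) == 1
        assert merged[0].start == 0.0 and merged[0].end == 5.0
        split, _ = residence_times(traj, topo, r_near=1.2, grace=0)
        assert len(split) == 2
        assert [e.duration for e in split] == pytest.approx([2.0, 2.0])

    def test_events_non_overlapping_per_precursor(self):
        topo, box, bpos, fpos = self._setup()
        pattern = [True, False, True, False, True, False]
        traj = _synthetic_traj(topo, box, pattern, bpos, fpos)
        events, _ = residence_times(traj, topo, r_near=1.2, grace=0)
        spans = sorted((e.start, e.end) for e in events)
        assert all(a2 >= b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))


class TestRadialChargeProfile:
    def test_conservation_and_step_profile(self):
        """Straight outward chains give the analytic ring-shell profile and
        the unnormalized bin sum equals the total brush charge."""
        sys_ = build_system(parse_layout("6HB-1*/1/1*-DS", n_domains=3),
                            geometry=GeometryParams.for_domains(3),
                            brush_contour=6.0, n_precursors=0, seed=0, box_xy=30.0)
        topo = sys_.topo
        traj = Trajectory(topo.position[None, ...], np.array([0.0]), sys_.box, {})
        bins = np.linspace(0, 15, 31)
        prof = radial_charge_profile(traj, topo, bins, window_fraction=1.0)
        brush = topo.mask(Species.DS_BEAD)
        assert prof.total_charge == pytest.approx(topo.charge[brush].sum())
        # analytic: beads sit at radii ~ ring + graft + k*bond (small jitter)
        centre = sys_.box.center()[:2]
        radii = np.hypot(*(topo.position[brush][:, :2] - centre).T)
        expect, _ = np.histogram(radii, bins=bins, weights=topo.charge[brush])
        assert np.allclose(prof.charge_per_bin, expect)

    def test_profile_mean_radius_weighting(self):
        prof_bins = np.array([0.0, 1.0, 2.0])
        from silicabrush.analysis import RadialChargeProfile

        prof = RadialChargeProfile(prof_bins, np.array([-1.0, -3.0]))
        assert prof.mean_radius() == pytest.approx((0.5 * 1 + 1.5 * 3) / 4)


class TestElectrostaticScan:
    def test_zero_probe_charge_zero_energy(self, small_system):
        rmap = assign_regions(small_system.spec, small_system.geometry.bundle_length)
        scan = electrostatic_scan(small_system.topo, small_system.topo.position,
                                  small_system.box, rmap, ForceFieldParams(),
                                  probe_charge=0.0)
        assert np.allclose(scan.energies, 0.0)

    def test_single_fixed_charge_matches_closed_form(self):
        """One core bead: the scan equals the screened-Coulomb closed form
        to 1e-9 k_BT at every probe position."""
        topo = CGTopology()
        box = BoxSpec([40, 40, 40])
        bead = np.array([20.0, 20.0, 17.0])
        topo.add_beads(Species.CORE, [bead], -1.0, 1.0, fixed=True)
        rmap = assign_regions(parse_layout("6HB"), 40.0)
        ff = ForceFieldParams(debye_length=2.0)
        scan = electrostatic_scan(topo, topo.position, box, rmap, ff,
                                  core_surface_radius=3.0, probe_charge=1.0,
                                  probe_offset=0.5, axial_spacing=4.0,
                                  azimuths=[0.0])
        for z, e in zip(scan.axial_positions, scan.energies):
            probe = np.array([20.0 + 3.5, 20.0, z])
            d = probe - bead
            d[2] -= 40.0 * round(d[2] / 40.0)
            r = np.linalg.norm(d)
            expect = ff.bjerrum_length * (-1.0) * math.exp(-r / 2.0) / r
            assert e == pytest.approx(expect, abs=1e-9)


class TestMgSweep:
    def test_table_columns_and_debye(self):
        def fake_run(di, seed):
            rmap = assign_regions(parse_layout("6HB-1*/2-DS", n_domains=3), 30.0)
            c = np.full(4, 10.0 / (1 + di))
            return RegionalCondensationResult(np.arange(4.0), c, c, rmap, seed=seed)

        table = mg_sweep(fake_run, [5.0, 16.0], seeds=[0, 1])
        assert len(table) == 4
        for di in (5.0, 16.0):
            sub = table[table.di_mM == di]
            assert np.allclose(sub.lambda_d_nm, debye_length(0.0, di))

    def test_single_level_degenerate(self):
        def fake_run(di, seed):
            rmap = assign_regions(parse_layout("6HB-1*/2-DS", n_domains=3), 30.0)
            c = np.ones(4)
            return RegionalCondensationResult(np.arange(4.0), c, c, rmap, seed=seed)

        table = mg_sweep(fake_run, [5.0], seeds=[3])
        assert len(table) == 1
        assert table.iloc[0].seed == 3


class TestTimeseriesOnSmallRun:
    def test_condensed_counts_match_bruteforce_every_frame(self, small_system):
        from silicabrush.dynamics import IntegratorParams, run

        topo = small_system.topo
        ip = IntegratorParams(n_steps=2000, frame_stride=400, seed=3)
        traj = run(topo, small_system.box, ForceFieldParams(), ip)
        rmap = assign_regions(small_system.spec, small_system.geometry.bundle_length)
        res = condensation_timeseries(traj, topo, rmap)
        core = topo.mask(Species.CORE)
        pre = topo.mask(Species.PRECURSOR)
        L = small_system.box.lengths[2]
        for f in range(traj.n_frames):
            nb = n0 = 0
            for p in traj.frames[f][pre]:
                d = traj.frames[f][core] - p
                d[:, 2] -= L * np.round(d[:, 2] / L)
                dist = np.sqrt((d ** 2).sum(1))
                if dist.min() <= res.r_condense:
                    z = traj.frames[f][core][np.argmin(dist), 2]
                    if rmap.label_of(z) == "BRUSH":
                        nb += 1
                    else:
                        n0 += 1
            assert (res.count_brush[f], res.count_bare[f]) == (nb, n0)
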