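"""Shared fixtures.

The expensive replica sets (the five-seed condensation experiments at the
frozen default parameters) are session-scoped and shared between the
condensation, retention and probe-scan acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from silicabrush.builder import GeometryParams, build_system
from silicabrush.forcefield import ForceFieldParams
from silicabrush.layout import parse_layout
from silicabrush.pipeline import (
    DEFAULT_CONFIG,
    ExperimentConfig,
    condensation_run,
)

ACCEPTANCE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def ds_runs():
    """Five seeded replicas of the DS 5*/17/5* experiment, frozen defaults."""
    cfg = DEFAULT_CONFIG.with_layout("6HB-5*/17/5*-DS")
    return [condensation_run(cfg, seed=s) for s in ACCEPTANCE_SEEDS]


@pytest.fixture(scope="session")
def ss_runs():
    """Companion SS replicas: same protocol, brush species swapped."""
    cfg = DEFAULT_CONFIG.with_layout("6HB-5*/17/5*-SS")
    return [condensation_run(cfg, seed=s) for s in ACCEPTANCE_SEEDS]


@pytest.fixture(scope="session")
def control_runs():
    """Zero-interaction control: no charges, no attraction, WCA only."""
    ff = ForceFieldParams(attraction_epsilon=0.0)
    cfg = ExperimentConfig(
        layout="6HB-2*/5/2*-DS", n_domains=9, n_precursors=80,
        n_steps=25_000, frame_stride=250, ff=ff,
    )
    runs = []
    for s in (0, 1, 2):
        spec = parse_layout(cfg.layout, n_domains=cfg.n_domains)
        system = build_system(
            spec, geometry=GeometryParams.for_domains(cfg.n_domains),
            brush_contour=cfg.brush_contour, n_precursors=cfg.n_precursors,
            seed=s, box_xy=cfg.box_xy,
        )
        # neutralize every charge: the control must have no electrostatics
        system.topo.charge[:] = 0.0
        from silicabrush.analysis import assign_regions, condensation_timeseries
        from silicabrush.dynamics import IntegratorParams, run

        ip = IntegratorParams(dt=cfg.dt, n_steps=cfg.n_steps,
                              frame_stride=cfg.frame_stride, seed=s)
        traj = run(system.topo, system.box, ff, ip)
        rmap = assign_regions(spec, system.geometry.bundle_length)
        res = condensation_timeseries(traj, system.topo, rmap, seed=s)
        runs.append((system, traj, res))
    return runs


@pytest.fixture(scope="session")
def small_system():
    """A cheap 3-domain DS bundle with a few precursors for unit tests."""
    return build_system(
        parse_layout("6HB-1*/1/1*-DS", n_domains=3),
        geometry=GeometryParams.for_domains(3),
        brush_contour=6.0, n_precursors=8, seed=11, box_xy=30.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
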