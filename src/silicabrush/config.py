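"""TOML run configuration with strict validation.

Every under-specified model constant is visible in the config and carried
into provenance, so a results file always names the exact parameter set that
produced it.  Unknown keys are rejected (typos must fail loudly, not fall
back to defaults).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Dict, List, Optional

from .dynamics import IntegratorParams
from .forcefield import ForceFieldParams
from .pipeline import ExperimentConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "default_config_toml"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


_SECTIONS = {
    "run": {"layout": str, "n_domains": int, "seeds": list, "outdir": str},
    "geometry": {"brush_contour": float, "box_xy": float, "n_precursors": int},
    "salt": {"mono_mM": float, "di_mM": float, "mode": str},
    "forcefield": {
        "bjerrum_length": float, "wca_epsilon": float, "attraction_epsilon": float,
        "attraction_range": float, "pair_cutoff": float, "switch_fraction": float,
        "precursor_precursor_attraction": bool,
    },
    "integrator": {"dt": float, "n_steps": int, "frame_stride": int,
                   "temperature": float, "gamma_per_radius": float, "skin": float},
    "analysis": {"r_condense": float, "r_near": float, "grace": int,
                 "window_fraction": float},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline invocation."""

    layout: str = "6HB-5*/17/5*-DS"
    n_domains: int = 27
    seeds: tuple = (0, 1, 2, 3, 4)
    outdir: str = "results"
    brush_contour: float = 9.0
    box_xy: float = 45.0
    n_precursors: int = 150
    mono_mM: float = 0.0
    di_mM: float = 5.0
    salt_mode: str = "implicit"
    forcefield_overrides: Dict[str, Any] = field(default_factory=dict)
    dt: float = 0.001
    n_steps: int = 50_000
    frame_stride: int = 500
    temperature: float = 298.0
    gamma_per_radius: float = 2.0
    skin: float = 1.0
    r_condense: float = 1.5
    r_near: float = 1.2
    grace: int = 0
    window_fraction: float = 0.5

    def experiment(self) -> ExperimentConfig:
        ff = ForceFieldParams(**self.forcefield_overrides)
        return ExperimentConfig(
            layout=self.layout, n_domains=self.n_domains,
            brush_contour=self.brush_contour, n_precursors=self.n_precursors,
            box_xy=self.box_xy, mono_mM=self.mono_mM, di_mM=self.di_mM,
            explicit_ions=(self.salt_mode == "explicit"),
            n_steps=self.n_steps, frame_stride=self.frame_stride, dt=self.dt,
            window_fraction=self.window_fraction, ff=ff,
        )

    def integrator(self, seed: int) -> IntegratorParams:
        return IntegratorParams(dt=self.dt, n_steps=self.n_steps,
                                frame_stride=self.frame_stride,
                                temperature=self.temperature,
                                gamma_per_radius=self.gamma_per_radius,
                                skin=self.skin, seed=seed)

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_section(name: str, table: Dict[str, Any]) -> None:
    if name not in _SECTIONS:
        raise ConfigError(f"unknown section [{name}]")
    allowed = _SECTIONS[name]
    for key, val in table.items():
        if key not in allowed:
            raise ConfigError(f"unknown key {name}.{key}")
        want = allowed[key]
        if want is float and isinstance(val, int) and not isinstance(val, bool):
            continue
        if not isinstance(val, want) or (want is int and isinstance(val, bool)):
            raise ConfigError(
                f"{name}.{key} must be {want.__name__}, got {type(val).__name__}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML config; raises ConfigError naming bad keys."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for section, table in data.items():
        if not isinstance(table, dict):
            raise ConfigError(f"top-level key {section} must be a section")
        _check_section(section, table)
    run = data.get("run", {})
    geo = data.get("geometry", {})
    salt = data.get("salt", {})
    ff = data.get("forcefield", {})
    integ = data.get("integrator", {})
    ana = data.get("analysis", {})
    if "mode" in salt and salt["mode"] not in ("implicit", "explicit"):
        raise ConfigError("salt.mode must be 'implicit' or 'explicit'")
    cfg = RunConfig(
        layout=run.get("layout", RunConfig.layout),
        n_domains=run.get("n_domains", RunConfig.n_domains),
        seeds=tuple(run.get("seeds", RunConfig.seeds)),
        outdir=run.get("outdir", RunConfig.outdir),
        brush_contour=float(geo.get("brush_contour", RunConfig.brush_contour)),
        box_xy=float(geo.get("box_xy", RunConfig.box_xy)),
        n_precursors=geo.get("n_precursors", RunConfig.n_precursors),
        mono_mM=float(salt.get("mono_mM", RunConfig.mono_mM)),
        di_mM=float(salt.get("di_mM", RunConfig.di_mM)),
        salt_mode=salt.get("mode", RunConfig.salt_mode),
        forcefield_overrides=dict(ff),
        dt=float(integ.get("dt", RunConfig.dt)),
        n_steps=integ.get("n_steps", RunConfig.n_steps),
        frame_stride=integ.get("frame_stride", RunConfig.frame_stride),
        temperature=float(integ.get("temperature", RunConfig.temperature)),
        gamma_per_radius=float(integ.get("gamma_per_radius", RunConfig.gamma_per_radius)),
        skin=float(integ.get("skin", RunConfig.skin)),
        r_condense=float(ana.get("r_condense", RunConfig.r_condense)),
        r_near=float(ana.get("r_near", RunConfig.r_near)),
        grace=ana.get("grace", RunConfig.grace),
        window_fraction=float(ana.get("window_fraction", RunConfig.window_fraction)),
    )
    try:
        ForceFieldParams(**cfg.forcefield_overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"forcefield: {exc}") from None
    return cfg


def default_config_toml() -> str:
    """A fully commented default config, suitable as a starting template."""
    return """\
[run]
layout = "6HB-5*/17/5*-DS"   # brush layout notation
n_domains = 27
seeds = [0, 1, 2, 3, 4]
outdir = "results"

[geometry]
brush_contour = 9.0          # nm contour length per brush chain
box_xy = 45.0                # nm, reflecting-wall box edge (x and y)
n_precursors = 150

[salt]
mono_mM = 0.0
di_mM = 5.0                  # working [Mg2+]
mode = "implicit"            # implicit screening or explicit ions

[forcefield]
attraction_epsilon = 1.4     # k_BT, calibrated precursor-DNA well depth
pair_cutoff = 5.0            # nm

[integrator]
dt = 0.001                   # tau
n_steps = 50000
frame_stride = 500

[analysis]
r_condense = 1.5             # nm from core bead centres
r_near = 1.2                 # nm from brush beads (residence events)
grace = 0                    # frames an excursion may last within one event
window_fraction = 0.5        # trailing analysis window
"""
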