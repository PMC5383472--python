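"""Experiment drivers reproducing the three idealized scenario sets, plus fixtures.

All three experiments share the same idealized stage: a 1-kHz nonpulsed
source of 240 dB re 1 uPa^2 s at 1 m with a 10% duty cycle, 15 log10(R)
spreading, a flat 50-m sea, and agents seeded uniformly in a 100-km disc
around the source.

* ``weighting_comparison`` — cumulative SEL and PTS-threshold exceedance for
  gray seal and harbor porpoise under the audiogram (A) and functional-group
  (M) weighting schemes.
* ``aversion_sweep`` — gray seal mean SEL under aversive movement with
  heading SDs from 10 (directionless) to 0.05 (directed fleeing).
* ``constrained_movement`` — matched constrained/unconstrained pairs with a
  reflecting hard boundary at 100 km (heading SD 10) or 75 km (SD 0.5).

Every comparison reuses one seed across its arms (paired seeds) so that
between-arm dB differences are estimated with minimal Monte-Carlo noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import Environment, make_uniform_disc_fixture
from .exposure import ExposureHistorySet, ScenarioConfig, mean_sel_curve, run_simulation, sel_at
from .risk import fraction_exceeding
from .soundfield import PropagationModel, SourceSpec
from .species import load_packaged_species, pts_threshold

__all__ = [
    "DEFAULT_DURATIONS_H",
    "DEFAULT_AVERSION_SDS",
    "DEFAULT_CONSTRAINT_PAIRS",
    "ExperimentSpec",
    "default_config",
    "default_environment",
    "run_weighting_comparison",
    "run_aversion_sweep",
    "run_constrained_movement",
    "generate_fixtures",
    "load_experiment",
    "write_run_log",
]

DEFAULT_DURATIONS_H = (1.0, 6.0, 12.0, 24.0, 48.0, 96.0, 168.0, 240.0)
DEFAULT_AVERSION_SDS = (10.0, 1.0, 0.5, 0.1, 0.05)
#: (hard boundary radius km, aversion heading SD) pairs for the constraint study
DEFAULT_CONSTRAINT_PAIRS = ((100.0, 10.0), (75.0, 0.5))

_FIXTURE_ENV = dict(radius_km=100.0, depth_m=50.0, cell_km=5.0, density_per_km2=0.05, cv=0.3)


def default_config(species: str = "gray seal", **overrides) -> ScenarioConfig:
    """The shared scenario configuration of the three experiment sets."""
    base = dict(
        source=SourceSpec(source_level_db=240.0, frequency_khz=1.0, duty_cycle=0.1),
        propagation=PropagationModel(k=15.0),
        species=species,
        weighting="M",
        n_agents=10_000,
        duration_h=240.0,
        dt_s=60.0,
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def default_environment(**overrides) -> Environment:
    """Uniform-density disc over a flat 50-m sea (the idealized study stage)."""
    params = {**_FIXTURE_ENV, **overrides}
    grid, bathy = make_uniform_disc_fixture(**params)
    return Environment(grid, bathy)


@dataclass
class ExperimentSpec:
    """One of the three experiment sets plus its sweep values and base config."""

    experiment: str
    base: ScenarioConfig
    sweep: tuple = ()
    durations_h: tuple = DEFAULT_DURATIONS_H
    environment_params: dict = field(default_factory=lambda: dict(_FIXTURE_ENV))

    def __post_init__(self):
        known = {"weighting_comparison", "aversion_sweep", "constrained_movement"}
        if self.experiment not in known:
            raise ValueError(f"unknown experiment {self.experiment!r}; known: {sorted(known)}")
        if self.experiment == "aversion_sweep":
            if self.sweep and any(s <= 0 for s in self.sweep):
                raise ValueError("aversion heading SDs must be positive")
        if self.experiment == "constrained_movement":
            for pair in self.sweep:
                if pair[0] <= 0 or pair[1] <= 0:
                    raise ValueError("boundary radii and heading SDs must be positive")


def _env_for(spec: ExperimentSpec, env: Environment | None) -> Environment:
    return env if env is not None else default_environment(**spec.environment_params)


def run_weighting_comparison(spec: ExperimentSpec, env: Environment | None = None):
    """PTS exceedance by species, weighting scheme and exposure duration.

    Returns ``(table, curves)``: a table with one row per species x scheme
    (threshold and percentage exceeding at each duration) and the per-arm
    mean-SEL curves.  Movement is the species' natural persistent walk; the
    A and M arms of one species share a seed and therefore trajectories, so
    their SEL curves differ by exactly the weighting offset.
    """
    env = _env_for(spec, env)
    species = load_packaged_species()
    names = list(spec.sweep) if spec.sweep else list(species)
    rows, curves = [], {}
    for name in names:
        if name not in species:
            raise ValueError(f"unknown species {name!r}; packaged: {sorted(species)}")
        profile = species[name]
        for scheme in ("A", "M"):
            cfg = replace(spec.base, species=name, weighting=scheme, aversion_sd=None)
            thr = pts_threshold(scheme, profile, cfg.source.frequency_khz)
            hist = run_simulation(cfg, profile, env)
            row = {"species": name, "scheme": scheme, "pts_threshold_db": thr}
            for d in spec.durations_h:
                row[f"pct_{d:g}h"] = fraction_exceeding(hist, thr, at_hours=d)
            rows.append(row)
            curves[(name, scheme)] = mean_sel_curve(hist, times_h=spec.durations_h)
    return pd.DataFrame(rows), curves


def run_aversion_sweep(spec: ExperimentSpec, env: Environment | None = None):
    """Mean SEL and central-95% band by aversion heading SD, with dB differences.

    Returns ``(curves, diffs)``: per-SD mean-SEL curves over the duration
    grid, and the difference table mean SEL(largest SD) - mean SEL(smallest
    SD) at 24 h and at the final time, i.e. directionless minus directed
    fleeing under paired seeds.
    """
    env = _env_for(spec, env)
    sds = tuple(spec.sweep) if spec.sweep else DEFAULT_AVERSION_SDS
    profile = load_packaged_species()[spec.base.species]
    curves = {}
    hists: dict[float, ExposureHistorySet] = {}
    for sd in sds:
        cfg = replace(spec.base, aversion_sd=float(sd))
        hists[sd] = run_simulation(cfg, profile, env)
        curves[sd] = mean_sel_curve(hists[sd], times_h=spec.durations_h)
    hi_sd, lo_sd = max(sds), min(sds)
    diffs = []
    for t in (24.0, spec.base.duration_h):
        if t <= spec.base.duration_h:
            d = float(np.mean(sel_at(hists[hi_sd], t)) - np.mean(sel_at(hists[lo_sd], t)))
            diffs.append({"time_h": t, "sd_high": hi_sd, "sd_low": lo_sd, "delta_db": d})
    return curves, pd.DataFrame(diffs).drop_duplicates(subset="time_h")


def run_constrained_movement(spec: ExperimentSpec, env: Environment | None = None):
    """Constrained-vs-unconstrained mean SEL differences under paired seeds.

    For each (boundary radius, heading SD) pair, runs a constrained arm with
    a reflecting hard boundary and a matched unconstrained arm, and reports
    constrained minus unconstrained mean SEL at 24 h and the final time.
    Returns ``(curves, diffs)``.
    """
    env = _env_for(spec, env)
    pairs = tuple(spec.sweep) if spec.sweep else DEFAULT_CONSTRAINT_PAIRS
    profile = load_packaged_species()[spec.base.species]
    curves, rows = {}, []
    for radius_km, sd in pairs:
        if radius_km > float(env.density.x_km[-1]) * np.sqrt(2):
            raise ValueError("boundary radius exceeds the environment extent")
        cfg_free = replace(spec.base, aversion_sd=float(sd), boundary_km=None)
        cfg_hard = replace(spec.base, aversion_sd=float(sd), boundary_km=float(radius_km))
        h_free = run_simulation(cfg_free, profile, env)
        h_hard = run_simulation(cfg_hard, profile, env)
        curves[(radius_km, sd, "constrained")] = mean_sel_curve(h_hard, times_h=spec.durations_h)
        curves[(radius_km, sd, "unconstrained")] = mean_sel_curve(h_free, times_h=spec.durations_h)
        for t in {24.0, spec.base.duration_h}:
            if t <= spec.base.duration_h:
                d = float(np.mean(sel_at(h_hard, t)) - np.mean(sel_at(h_free, t)))
                rows.append(
                    {"radius_km": radius_km, "heading_sd": sd, "time_h": t, "delta_db": d}
                )
    return curves, pd.DataFrame(rows).sort_values(["radius_km", "time_h"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# fixtures, config files, logging

_EXPERIMENT_CONFIGS = {
    "weighting": {
        "experiment": "weighting_comparison",
        "species": "gray seal",
        "sweep": ["gray seal", "harbor porpoise"],
    },
    "aversion": {
        "experiment": "aversion_sweep",
        "species": "gray seal",
        "sweep": list(DEFAULT_AVERSION_SDS),
    },
    "constrained": {
        "experiment": "constrained_movement",
        "species": "gray seal",
        "sweep": [list(p) for p in DEFAULT_CONSTRAINT_PAIRS],
    },
}


def generate_fixtures(out_dir) -> list[Path]:
    """Write the packaged fixture tables, the idealized grids and the three
    experiment configs to ``out_dir``; content is deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (
        "species.csv",
        "audiogram_gray_seal_synthetic.csv",
        "audiogram_harbor_porpoise_synthetic.csv",
        "m_weighting_groups.csv",
        "effect_criteria.csv",
    ):
        dest = out / name
        dest.write_text(resources.files("exposim.data").joinpath(name).read_text())
        written.append(dest)
    grid, bathy = make_uniform_disc_fixture(**_FIXTURE_ENV)
    dens = grid.to_frame()
    dest = out / "density_disc.csv"
    dens.to_csv(dest, index=False, float_format="%.6g")
    written.append(dest)
    xx, yy = np.meshgrid(bathy.x_km, bathy.y_km)
    bdf = pd.DataFrame({"x_km": xx.ravel(), "y_km": yy.ravel(), "depth_m": bathy.depth_m.ravel()})
    dest = out / "bathymetry_flat.csv"
    bdf.to_csv(dest, index=False, float_format="%.6g")
    written.append(dest)
    for stem, extra in _EXPERIMENT_CONFIGS.items():
        cfg = {
            "experiment": extra["experiment"],
            "source": {"source_level_db": 240.0, "frequency_khz": 1.0, "duty_cycle": 0.1},
            "propagation": {"k": 15.0},
            "species": extra["species"],
            "weighting": "M",
            "n_agents": 10000,
            "duration_h": 240.0,
            "dt_s": 60.0,
            "seed": 0,
            "sweep": extra["sweep"],
            "durations_h": list(DEFAULT_DURATIONS_H),
            "environment": dict(_FIXTURE_ENV),
        }
        dest = out / f"{stem}.yaml"
        dest.write_text(yaml.safe_dump(cfg, sort_keys=True))
        written.append(dest)
    return written


def load_experiment(path) -> ExperimentSpec:
    """Parse an experiment config file (YAML) into an :class:`ExperimentSpec`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    src = SourceSpec(**raw.get("source", {}))
    prop = PropagationModel(**raw.get("propagation", {}))
    base = ScenarioConfig(
        source=src,
        propagation=prop,
        species=raw.get("species", "gray seal"),
        weighting=raw.get("weighting", "M"),
        n_agents=int(raw.get("n_agents", 10000)),
        duration_h=float(raw.get("duration_h", 240.0)),
        dt_s=float(raw.get("dt_s", 60.0)),
        seed=int(raw.get("seed", 0)),
    )
    sweep = raw.get("sweep", [])
    if raw["experiment"] == "constrained_movement":
        sweep = tuple(tuple(p) for p in sweep)
    else:
        sweep = tuple(sweep)
    return ExperimentSpec(
        experiment=raw["experiment"],
        base=base,
        sweep=sweep,
        durations_h=tuple(raw.get("durations_h", DEFAULT_DURATIONS_H)),
        environment_params=raw.get("environment", dict(_FIXTURE_ENV)),
    )


def write_run_log(out_dir, spec: ExperimentSpec) -> Path:
    """Write a JSON log with seed, config echo and package version."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "package": "exposim",
        "version": __version__,
        "experiment": spec.experiment,
        "seed": spec.base.seed,
        "config": asdict(spec.base),
        "sweep": list(map(list, spec.sweep)) if spec.experiment == "constrained_movement" else list(spec.sweep),
        "durations_h": list(spec.durations_h),
        "environment": dict(spec.environment_params),
    }
    dest = out / "run_log.json"
    dest.write_text(json.dumps(log, indent=2, default=str))
    return dest
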