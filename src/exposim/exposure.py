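"""The simulation engine: advance agents, query the field, accumulate weighted SEL.

Each time step every agent (i) moves one directed-random-walk step, (ii) has
its received level looked up from the propagation model at its new position,
(iii) has that level frequency-weighted for the species' hearing, and (iv)
adds duty_cycle x dt seconds of the weighted intensity to its running energy
accumulator.  Cumulative SEL is the accumulator expressed in dB:

    SEL = 10 log10( sum_i 10^(L_i / 10) * s_i )      [dB re 1 uPa^2 s]

for weighted levels L_i applied over s_i active seconds.  The accumulator is
kept on the linear scale with zero as the "no exposure yet" sentinel, so dB
arithmetic never involves -inf until a user asks for it.

Runs are reproducible given the scenario seed.  Comparison experiments reuse
one seed across arms (paired seeds): seeding, initial state, heading noise
and dive phases then share random streams, which cancels most Monte-Carlo
variance in between-arm dB differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import DomainBoundary, Environment, sample_positions
from .movement import AgentState, MovementParams, dive_depth, step_agent
from .soundfield import (
    PropagationModel,
    SourceSpec,
    active_exposure_seconds,
    received_level,
)
from .species import SpeciesProfile, a_weighting, m_weighting

__all__ = [
    "ScenarioConfig",
    "ExposureHistorySet",
    "accumulate_sel",
    "run_simulation",
    "mean_sel_curve",
    "sel_at",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one simulation arm."""

    source: SourceSpec
    propagation: PropagationModel
    species: str
    weighting: str = "M"
    n_agents: int = 10_000
    duration_h: float = 240.0
    dt_s: float = 60.0
    aversion_sd: float | None = None
    boundary_km: float | None = None
    seed: int = 0
    record_every: int | None = None
    record_rl: bool = False

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        if self.dt_s <= 0:
            raise ValueError("time step must be positive")
        if self.weighting not in ("M", "A"):
            raise ValueError("weighting scheme must be 'M' or 'A'")
        if self.aversion_sd is not None and self.aversion_sd < 0:
            raise ValueError("aversion SD must be nonnegative")

    def n_steps(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.dt_s))

    def default_record_every(self) -> int:
        # store every step for short scenarios, thin long ones; the running
        # accumulator is never thinned so the final SEL stays exact
        if self.record_every is not None:
            return self.record_every
        return 1 if self.duration_h <= 48.0 else 10


@dataclass
class ExposureHistorySet:
    """Recorded exposure trajectories for one cohort.

    ``sel_db`` has shape (n_agents, n_times); -inf marks agents that have
    received no energy yet at that time.  ``final_sel_db`` comes from the
    unthinned accumulator at the last step.
    """

    times_h: np.ndarray
    sel_db: np.ndarray
    final_sel_db: np.ndarray
    start_cell: np.ndarray
    weighting_db: float
    config: ScenarioConfig
    rl_db: np.ndarray | None = None

    @property
    def n_agents(self) -> int:
        return self.sel_db.shape[0]

    def to_frame(self):
        """Long-format (agent_id, t_hours, sel_db[, rl_db]) table."""
        import pandas as pd

        n, t = self.sel_db.shape
        out = pd.DataFrame(
            {
                "agent_id": np.repeat(np.arange(n), t),
                "t_hours": np.tile(self.times_h, n),
                "sel_db": self.sel_db.ravel(),
            }
        )
        if self.rl_db is not None:
            out["rl_db"] = self.rl_db.ravel()
        return out


def accumulate_sel(prev_sel_db: float | None, weighted_rl_db: float, exposure_seconds: float) -> float:
    """Add ``exposure_seconds`` of a weighted level to a cumulative SEL (energy sum).

    ``prev_sel_db`` of None means no prior exposure, so one second at level L
    returns exactly L.
    """
    if exposure_seconds < 0:
        raise ValueError("exposure seconds must be nonnegative")
    prev = 0.0 if prev_sel_db is None else 10.0 ** (prev_sel_db / 10.0)
    total = prev + 10.0 ** (weighted_rl_db / 10.0) * exposure_seconds
    if total == 0.0:
        raise ValueError("no energy accumulated; cumulative SEL undefined")
    return 10.0 * np.log10(total)


def _weighting_value(config: ScenarioConfig, profile: SpeciesProfile) -> float:
    f = config.source.frequency_khz
    if config.weighting == "M":
        return m_weighting(f, profile.group)
    return a_weighting(f, profile.audiogram)


def run_simulation(
    config: ScenarioConfig,
    profile: SpeciesProfile,
    env: Environment,
) -> ExposureHistorySet:
    """Run one scenario arm and return the cohort's exposure histories.

    Aversion: when ``config.aversion_sd`` is set and the species responds to
    noise, every heading draw is centred on the bearing directly away from
    the source with that SD; otherwise the walk is persistent (centred on the
    previous heading) with the species' natural heading SD.  A
    ``boundary_km`` adds a reflecting hard boundary around the source.
    """
    if profile.name != config.species:
        raise ValueError(
            f"config names species {config.species!r} but profile is {profile.name!r}"
        )
    boundary = (
        DomainBoundary(config.boundary_km)
        if config.boundary_km is not None
        else env.boundary
    )
    if (
        boundary.radius_km is not None
        and boundary.radius_km > float(np.max(np.hypot(*np.meshgrid(env.density.x_km, env.density.y_km))))
    ):
        raise ValueError("hard boundary lies outside the density grid extent")

    seed_rng, move_rng, dive_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    ]
    positions, cells = sample_positions(
        env.density, config.n_agents, seed_rng, bathymetry=env.bathymetry, boundary=boundary
    )
    state = AgentState.initialize(positions, profile, seed_rng)
    params = MovementParams(
        speed_ms=profile.swim_speed_typical_ms,
        heading_sd=(
            config.aversion_sd
            if (config.aversion_sd is not None and profile.responds_to_noise)
            else profile.heading_sd_natural
        ),
        aversive=config.aversion_sd is not None and profile.responds_to_noise,
    )
    w_db = _weighting_value(config, profile)
    src_xy = (config.source.x_km, config.source.y_km)
    seconds_per_step = active_exposure_seconds(0.0, config.dt_s, config.source)

    n_steps = config.n_steps()
    every = config.default_record_every()
    rec_steps = list(range(every, n_steps + 1, every))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_idx = {s: j for j, s in enumerate(rec_steps)}
    sel_rec = np.empty((config.n_agents, len(rec_steps)))
    rl_rec = np.empty_like(sel_rec) if config.record_rl else None

    for step in range(1, n_steps + 1):
        step_agent(state, params, config.dt_s, src_xy, env.bathymetry, boundary, move_rng)
        dive_depth(state, profile, config.dt_s, env.bathymetry, dive_rng)
        rl = received_level(config.source, config.propagation, state.x_km, state.y_km)
        state.energy += 10.0 ** ((rl + w_db) / 10.0) * seconds_per_step
        j = rec_idx.get(step)
        if j is not None:
            sel_rec[:, j] = state.sel_db
            if rl_rec is not None:
                rl_rec[:, j] = rl

    return ExposureHistorySet(
        times_h=np.asarray(rec_steps, dtype=float) * config.dt_s / 3600.0,
        sel_db=sel_rec,
        final_sel_db=state.sel_db.copy(),
        start_cell=cells,
        weighting_db=float(w_db),
        config=config,
        rl_db=rl_rec,
    )


def sel_at(histories: ExposureHistorySet, at_hours: float) -> np.ndarray:
    """Per-agent cumulative SEL at the recorded time nearest ``at_hours``."""
    t = histories.times_h
    if at_hours > t[-1] + 1e-9:
        raise ValueError(f"requested time {at_hours} h beyond simulated {t[-1]} h")
    return histories.sel_db[:, int(np.argmin(np.abs(t - at_hours)))]


def mean_sel_curve(histories: ExposureHistorySet, times_h=None):
    """Mean SEL over agents (dB domain) with the central-95% band, per time point.

    The band endpoints are the empirical 2.5 and 97.5 percentiles of the
    per-agent SELs (order statistics), reported only for cohorts of at least
    20 agents.
    """
    import pandas as pd

    if histories.n_agents == 0:
        raise ValueError("empty history set")
    if times_h is None:
        cols = np.arange(histories.times_h.size)
    else:
        cols = [int(np.argmin(np.abs(histories.times_h - t))) for t in np.atleast_1d(times_h)]
    sel = histories.sel_db[:, cols]
    mean = sel.mean(axis=0)
    if histories.n_agents >= 20:
        lo, hi = np.percentile(sel, [2.5, 97.5], axis=0)
    else:
        lo = np.full(mean.shape, np.nan)
        hi = np.full(mean.shape, np.nan)
    return pd.DataFrame(
        {
            "time_h": histories.times_h[cols],
            "mean_sel_db": mean,
            "lo_2p5_db": lo,
            "hi_97p5_db": hi,
        }
    )
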