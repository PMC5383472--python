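"""Agent movement: directed random walk, aversion, dive cycle, constraints.

Horizontal movement is a directed random walk at constant speed: at every
time step each agent draws a new heading from a wrapped normal distribution
whose mean is either the agent's previous heading (natural, persistent
movement) or the bearing pointing directly away from the sound source
(aversive, responsive movement), and whose standard deviation sigma (radians)
sets how directed the walk is.  sigma = 0 gives straight-line travel; sigma of
10 is indistinguishable from a uniform heading distribution (mean resultant
length exp(-sigma^2/2) ~ 2e-22), i.e. directionless diffusion.

Vertical movement is a triangular dive cycle (descend, ascend, surface
interval) bounded by the species' maximum dive depth and the local seafloor.
Because the sound field is depth-independent, diving affects realism but not
the accumulated exposure.

``AgentState`` holds the state of a whole cohort as arrays; all operations
are vectorized across agents.  A single animal is simply a cohort of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import Bathymetry, DomainBoundary
from .species import SpeciesProfile

__all__ = [
    "AgentState",
    "MovementParams",
    "draw_heading",
    "step_agent",
    "apply_constraints",
    "dive_depth",
    "wrap_angle",
]

_STUCK_RETRIES = 8


def wrap_angle(theta):
    """Wrap angles to [-pi, pi); values already in range pass through bit-exact."""
    t = np.asarray(theta, dtype=float)
    wrapped = np.mod(t + np.pi, 2.0 * np.pi) - np.pi
    return np.where((t >= -np.pi) & (t < np.pi), t, wrapped)


@dataclass
class MovementParams:
    """Directed-random-walk parameters for one scenario arm."""

    speed_ms: float
    heading_sd: float
    aversive: bool = False

    def __post_init__(self):
        if self.speed_ms < 0:
            raise ValueError("speed must be nonnegative")
        if self.heading_sd < 0:
            raise ValueError("heading SD must be nonnegative")


@dataclass
class AgentState:
    """Positions, headings, depths and exposure accumulators for a cohort of agents.

    ``energy`` is the running weighted exposure on the linear scale
    (uPa^2 s referenced units); zero encodes "no exposure yet", avoiding
    -inf dB arithmetic.
    """

    x_km: np.ndarray
    y_km: np.ndarray
    heading: np.ndarray
    depth_m: np.ndarray
    dive_phase_s: np.ndarray
    dive_peak_frac: np.ndarray
    energy: np.ndarray

    @property
    def n(self) -> int:
        return self.x_km.size

    @property
    def sel_db(self) -> np.ndarray:
        """Cumulative weighted SEL in dB; -inf where no energy has been received."""
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.energy)

    @classmethod
    def initialize(
        cls,
        positions: np.ndarray,
        profile: SpeciesProfile,
        rng: np.random.Generator,
    ) -> "AgentState":
        """Start a cohort at seeded positions with random headings and dive phases."""
        n = positions.shape[0]
        cycle = profile.typical_dive_duration_s + profile.surface_time_s
        return cls(
            x_km=positions[:, 0].astype(float).copy(),
            y_km=positions[:, 1].astype(float).copy(),
            heading=rng.uniform(-np.pi, np.pi, size=n),
            depth_m=np.zeros(n),
            dive_phase_s=rng.uniform(0.0, cycle, size=n),
            dive_peak_frac=rng.uniform(0.5, 1.0, size=n),
            energy=np.zeros(n),
        )


def draw_heading(mean, sd: float, rng: np.random.Generator, size=None):
    """Sample wrapped-normal headings with the given circular mean and SD (radians).

    sd = 0 returns the mean exactly (a standard-normal draw is still consumed
    so that paired-seed comparison arms stay aligned on the random stream).
    """
    if sd < 0:
        raise ValueError("heading SD must be nonnegative")
    if size is None:
        size = np.shape(mean) if np.shape(mean) else None
    z = rng.standard_normal(size=size)
    out = wrap_angle(np.asarray(mean, dtype=float) + sd * z)
    return float(out) if out.ndim == 0 else out


def apply_constraints(
    x_km,
    y_km,
    bathymetry: Bathymetry | None = None,
    boundary: DomainBoundary | None = None,
    prev_x_km=None,
    prev_y_km=None,
):
    """Clamp proposed positions to the legal domain.

    A proposal beyond the hard boundary radius has its radial component
    reflected specularly about the boundary circle (range 2R - r at the same
    bearing), so a step shorter than R always lands inside.  A proposal on
    land reverts to the previous position when one is given (the stepping
    routine retries headings before accepting that fallback).
    """
    x = np.atleast_1d(np.asarray(x_km, dtype=float)).copy()
    y = np.atleast_1d(np.asarray(y_km, dtype=float)).copy()
    if boundary is not None and boundary.radius_km is not None:
        r = np.hypot(x, y)
        outside = r > boundary.radius_km
        if np.any(outside):
            r_out = r[outside]
            scale = np.maximum(2.0 * boundary.radius_km - r_out, 0.0) / r_out
            x[outside] *= scale
            y[outside] *= scale
    if bathymetry is not None and prev_x_km is not None:
        on_land = ~np.atleast_1d(bathymetry.is_water(x, y))
        if np.any(on_land):
            x[on_land] = np.atleast_1d(np.asarray(prev_x_km, dtype=float))[on_land]
            y[on_land] = np.atleast_1d(np.asarray(prev_y_km, dtype=float))[on_land]
    if np.isscalar(x_km):
        return float(x[0]), float(y[0])
    return x, y


def _propose(state, heading, step_km, boundary):
    x = state.x_km + step_km * np.cos(heading)
    y = state.y_km + step_km * np.sin(heading)
    if boundary is not None and boundary.radius_km is not None:
        r = np.hypot(x, y)
        outside = r > boundary.radius_km
        if np.any(outside):
            scale = np.maximum(2.0 * boundary.radius_km - r[outside], 0.0) / r[outside]
            x[outside] *= scale
            y[outside] *= scale
    return x, y


def step_agent(
    state: AgentState,
    params: MovementParams,
    dt_s: float,
    source_xy_km: tuple[float, float],
    bathymetry: Bathymetry | None = None,
    boundary: DomainBoundary | None = None,
    rng: np.random.Generator | None = None,
) -> AgentState:
    """Advance the cohort one time step in place.

    The heading mean is the previous heading (natural movement) or the exact
    away-from-source bearing recomputed every step (aversive movement); the
    displacement is speed x dt along the freshly drawn heading, after which
    boundary and land constraints are applied.  Agents whose proposal lands
    ashore redraw their heading up to 8 times and finally take a reflected
    (reversed) heading without moving.
    """
    if dt_s <= 0:
        raise ValueError("time step must be positive")
    rng = np.random.default_rng() if rng is None else rng
    if params.aversive:
        mean = np.arctan2(state.y_km - source_xy_km[1], state.x_km - source_xy_km[0])
    else:
        mean = state.heading
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (state.n,))
    heading = draw_heading(mean, params.heading_sd, rng, size=state.n)
    step_km = params.speed_ms * dt_s / 1000.0
    x, y = _propose(state, heading, step_km, boundary)
    if bathymetry is not None:
        stuck = ~np.atleast_1d(bathymetry.is_water(x, y))
        tries = 0
        while np.any(stuck) and tries < _STUCK_RETRIES:
            redraw = draw_heading(mean[stuck], params.heading_sd, rng, size=int(stuck.sum()))
            heading[stuck] = redraw
            xs = state.x_km[stuck] + step_km * np.cos(redraw)
            ys = state.y_km[stuck] + step_km * np.sin(redraw)
            xs, ys = apply_constraints(xs, ys, boundary=boundary)
            x[stuck], y[stuck] = xs, ys
            stuck2 = stuck.copy()
            stuck2[stuck] = ~np.atleast_1d(bathymetry.is_water(xs, ys))
            stuck = stuck2
            tries += 1
        if np.any(stuck):  # give up: reverse heading, stay put
            heading[stuck] = wrap_angle(heading[stuck] + np.pi)
            x[stuck] = state.x_km[stuck]
            y[stuck] = state.y_km[stuck]
    state.x_km, state.y_km, state.heading = x, y, heading
    return state


def dive_depth(
    state: AgentState,
    profile: SpeciesProfile | None,
    dt_s: float,
    bathymetry: Bathymetry | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the dive cycle one step and return the new depths (m).

    The cycle is triangular: descend to a per-dive peak depth at mid-dive,
    ascend, then spend the surface interval at 0 m.  The peak depth is a
    per-cycle uniform fraction (0.5-1.0) of the smaller of the species'
    maximum dive depth and the local seafloor depth, so agents never dive
    below the seabed.  With ``profile`` None the cohort stays at the surface.
    """
    if dt_s <= 0:
        raise ValueError("time step must be positive")
    if profile is None:
        state.depth_m = np.zeros(state.n)
        return state.depth_m
    dive_s = profile.typical_dive_duration_s
    cycle_s = dive_s + profile.surface_time_s
    phase = state.dive_phase_s + dt_s
    rolled = phase >= cycle_s
    if np.any(rolled):
        phase[rolled] = np.mod(phase[rolled], cycle_s)
        state.dive_peak_frac[rolled] = rng.uniform(0.5, 1.0, size=int(rolled.sum()))
    state.dive_phase_s = phase
    floor = (
        bathymetry.depth_at(state.x_km, state.y_km)
        if bathymetry is not None
        else np.full(state.n, np.inf)
    )
    cap = np.minimum(profile.max_dive_depth_m, np.maximum(floor, 0.0))
    peak = state.dive_peak_frac * cap
    diving = phase < dive_s
    tri = 1.0 - np.abs(2.0 * phase / dive_s - 1.0)
    depth = np.where(diving, peak * tri, 0.0)
    state.depth_m = np.minimum(depth, np.maximum(floor, 0.0))
    return state.depth_m
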