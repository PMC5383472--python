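"""Sound source, duty cycle, geometric-spreading propagation and field libraries.

Received level at horizontal range r follows the geometric-spreading family

    RL(r) = SL - k log10(max(r, r_ref) / r_ref) - alpha * r_km,

with spreading coefficient k in dB per decade of range (10 cylindrical,
15 intermediate, 20 spherical), reference range r_ref (1 m by default) and an
optional linear absorption term alpha in dB/km (0 by default).  The field is
depth-independent: the idealized scenarios use a flat shallow sea and a
far-field geometric model, so vertical structure is not resolved.

Source and received levels are on the SEL scale, dB re 1 uPa^2 s for a
1-second exposure; the duty cycle converts wall-clock time into active
exposure seconds as a deterministic energy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "SourceSpec",
    "PropagationModel",
    "FieldLibrary",
    "received_level",
    "active_exposure_seconds",
    "precompute_field",
]


@dataclass(frozen=True)
class SourceSpec:
    """An anthropogenic sound source: level, frequency, duty cycle, position."""

    source_level_db: float
    frequency_khz: float
    duty_cycle: float = 1.0
    x_km: float = 0.0
    y_km: float = 0.0
    pulsed: bool = False

    def __post_init__(self):
        if not np.isfinite(self.source_level_db):
            raise ValueError("source level must be finite")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must lie in [0, 1]")
        if self.frequency_khz <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class PropagationModel:
    """Geometric spreading with coefficient k (dB/decade) and optional absorption."""

    k: float = 15.0
    r_ref_m: float = 1.0
    absorption_db_per_km: float = 0.0

    def __post_init__(self):
        if self.k <= 0 or self.r_ref_m <= 0:
            raise ValueError("spreading coefficient and reference range must be positive")
        if self.absorption_db_per_km < 0:
            raise ValueError("absorption must be nonnegative")


def received_level(
    source: SourceSpec,
    model: PropagationModel,
    x_km,
    y_km,
) -> float | np.ndarray:
    """Received level (dB) at planar positions, from horizontal range only.

    Ranges below the reference range are clamped to it, so RL never exceeds
    the source level.
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    r_m = np.hypot(x - source.x_km, y - source.y_km) * 1000.0
    r = np.maximum(r_m, model.r_ref_m)
    rl = (
        source.source_level_db
        - model.k * np.log10(r / model.r_ref_m)
        - model.absorption_db_per_km * r / 1000.0
    )
    return float(rl) if np.isscalar(x_km) and np.isscalar(y_km) else rl


def active_exposure_seconds(t0_s: float, t1_s: float, source: SourceSpec) -> float:
    """Seconds of active emission in [t0, t1] under the fractional-duty convention.

    The duty cycle is realized as a deterministic energy fraction: every
    interval contributes (t1 - t0) * d active seconds, which matches an
    explicit ping schedule in cumulative energy whenever the interval is
    long relative to the ping period.
    """
    if t1_s < t0_s:
        raise ValueError("interval end must not precede its start")
    return (t1_s - t0_s) * source.duty_cycle


@dataclass
class FieldLibrary:
    """Precomputed received-level grid with bilinear interpolation between nodes."""

    x_km: np.ndarray
    y_km: np.ndarray
    levels_db: np.ndarray
    source: SourceSpec | None = None
    model: PropagationModel | None = None

    def __post_init__(self):
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        if self.x_km.size < 2 or self.y_km.size < 2:
            raise ValueError("field grid needs at least 2 nodes per axis")
        if self.levels_db.shape != (self.y_km.size, self.x_km.size):
            raise ValueError("levels grid shape must be (ny, nx)")
        self._interp = RegularGridInterpolator(
            (self.y_km, self.x_km), self.levels_db, method="linear", bounds_error=True
        )

    def level_at(self, x_km, y_km):
        """Interpolated received level (dB); raises outside the grid extent."""
        x = np.asarray(x_km, dtype=float)
        y = np.asarray(y_km, dtype=float)
        pts = np.column_stack([np.ravel(y), np.ravel(x)])
        out = self._interp(pts).reshape(np.shape(x))
        return float(out) if np.isscalar(x_km) and np.isscalar(y_km) else out

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_km, self.y_km)
        return pd.DataFrame(
            {"x_km": xx.ravel(), "y_km": yy.ravel(), "rl_db": self.levels_db.ravel()}
        )


def precompute_field(
    source: SourceSpec,
    model: PropagationModel,
    x_km: np.ndarray,
    y_km: np.ndarray,
) -> FieldLibrary:
    """Evaluate the propagation formula on a regular grid and wrap it for lookup.

    Node values equal :func:`received_level` exactly; off-node queries are
    bilinear in (x, y), which is accurate to a fraction of a dB in the far
    field at km-scale spacing but smooths the 1/r singularity near the
    source.
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("field grid must be nonempty")
    xx, yy = np.meshgrid(x, y)
    levels = received_level(source, model, xx, yy)
    return FieldLibrary(x, y, levels, source=source, model=model)
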