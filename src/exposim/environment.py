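"""Density surfaces, bathymetry, boundaries, agent seeding and fixture generation.

Coordinates are local planar x, y in kilometres with the sound source at the
origin; real-world grids are assumed to be pre-projected.  A density surface
gives animals per km^2 plus a coefficient of variation (CV) per cell; agents
are seeded proportionally to density and the CV drives lognormal resampling
of the surface when confidence intervals are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityGrid",
    "Bathymetry",
    "DomainBoundary",
    "Environment",
    "sample_positions",
    "resample_density",
    "abundance",
    "make_uniform_disc_fixture",
]


@dataclass
class DensityGrid:
    """Regular grid of animal density (animals/km^2) with per-cell CV.

    ``x_km`` and ``y_km`` are 1-D cell-centre coordinates with uniform
    spacing; ``density`` and ``cv`` are (ny, nx) arrays.
    """

    x_km: np.ndarray
    y_km: np.ndarray
    density: np.ndarray
    cv: np.ndarray

    def __post_init__(self):
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        for ax in (self.x_km, self.y_km):
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError("grid axes must be 1-D and nonempty")
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(d <= 0) or not np.allclose(d, d[0]):
                    raise ValueError("grid axes must be strictly increasing and regular")
        shape = (self.y_km.size, self.x_km.size)
        if self.density.shape != shape or self.cv.shape != shape:
            raise ValueError(f"density/cv must have shape {shape}")
        if np.any(self.density < 0):
            raise ValueError("densities must be nonnegative")
        if not np.any(self.density > 0):
            raise ValueError("density grid must contain at least one positive cell")
        if np.any(self.cv < 0):
            raise ValueError("coefficients of variation must be nonnegative")

    @property
    def cell_km(self) -> float:
        ax = self.x_km if self.x_km.size > 1 else self.y_km
        return float(ax[1] - ax[0]) if ax.size > 1 else 1.0

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_km, self.y_km)
        return pd.DataFrame(
            {
                "x_km": xx.ravel(),
                "y_km": yy.ravel(),
                "density_per_km2": self.density.ravel(),
                "cv": self.cv.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df) -> "DensityGrid":
        x = np.unique(df["x_km"].to_numpy())
        y = np.unique(df["y_km"].to_numpy())
        dens = np.full((y.size, x.size), np.nan)
        cv = np.zeros_like(dens)
        ix = np.searchsorted(x, df["x_km"].to_numpy())
        iy = np.searchsorted(y, df["y_km"].to_numpy())
        dens[iy, ix] = df["density_per_km2"].to_numpy()
        cv[iy, ix] = df["cv"].to_numpy()
        if np.any(np.isnan(dens)):
            raise ValueError("density table does not cover a full regular grid")
        return cls(x, y, dens, cv)


def _nearest_index(axis: np.ndarray, v: np.ndarray) -> np.ndarray:
    hi = np.clip(np.searchsorted(axis, v), 1, axis.size - 1) if axis.size > 1 else np.zeros(np.shape(v), dtype=int)
    if axis.size == 1:
        return hi
    lo = hi - 1
    return np.where(np.abs(v - axis[lo]) <= np.abs(axis[hi] - v), lo, hi)


@dataclass
class Bathymetry:
    """Seafloor depth grid in metres, positive down; land is encoded as depth <= 0.

    Queries outside the gridded extent take the nearest edge value, which
    supports idealized open-water scenarios where a flat grid stands for an
    unbounded sea.
    """

    x_km: np.ndarray
    y_km: np.ndarray
    depth_m: np.ndarray

    def __post_init__(self):
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if not np.all(np.isfinite(self.depth_m)):
            raise ValueError("bathymetry must be finite")
        if self.depth_m.shape != (self.y_km.size, self.x_km.size):
            raise ValueError("depth grid shape must be (ny, nx)")

    def depth_at(self, x_km, y_km):
        """Nearest-cell seafloor depth (m) at planar positions."""
        x = np.asarray(x_km, dtype=float)
        y = np.asarray(y_km, dtype=float)
        ix = _nearest_index(self.x_km, x)
        iy = _nearest_index(self.y_km, y)
        out = self.depth_m[iy, ix]
        return float(out) if np.isscalar(x_km) and np.isscalar(y_km) else out

    def is_water(self, x_km, y_km):
        return self.depth_at(x_km, y_km) > 0


@dataclass(frozen=True)
class DomainBoundary:
    """Optional hard radius (km, measured from the source at the origin)."""

    radius_km: float | None = None

    def __post_init__(self):
        if self.radius_km is not None and self.radius_km <= 0:
            raise ValueError("boundary radius must be positive")


@dataclass
class Environment:
    """The static stage a scenario plays out on: density, bathymetry, boundary."""

    density: DensityGrid
    bathymetry: Bathymetry
    boundary: DomainBoundary = field(default_factory=DomainBoundary)


def sample_positions(
    grid: DensityGrid,
    n: int,
    rng: np.random.Generator,
    bathymetry: Bathymetry | None = None,
    boundary: DomainBoundary | None = None,
):
    """Seed ``n`` agent positions proportionally to density.

    Cells are drawn with probability proportional to density x cell area,
    positions uniform within the chosen cell.  Cells on land (bathymetry
    depth <= 0) or with centre beyond a hard boundary are excluded before
    drawing.  Returns ``(positions, cell_index)`` where positions is an
    (n, 2) array of x, y in km and cell_index the flat grid index each
    agent started in (used for risk maps).
    """
    if n < 1:
        raise ValueError("need at least one agent")
    weights = (grid.density * grid.cell_area_km2).ravel().copy()
    xx, yy = np.meshgrid(grid.x_km, grid.y_km)
    if bathymetry is not None:
        weights[~np.atleast_1d(bathymetry.is_water(xx.ravel(), yy.ravel()))] = 0.0
    if boundary is not None and boundary.radius_km is not None:
        r = np.hypot(xx.ravel(), yy.ravel())
        weights[r > boundary.radius_km] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("no seedable density (all-zero after land/boundary masking)")
    cells = rng.choice(weights.size, size=n, p=weights / total)
    half = grid.cell_km / 2.0
    x = xx.ravel()[cells] + rng.uniform(-half, half, size=n)
    y = yy.ravel()[cells] + rng.uniform(-half, half, size=n)
    return np.column_stack([x, y]), cells


def resample_density(grid: DensityGrid, rng: np.random.Generator) -> DensityGrid:
    """Draw one realization of the density surface from its CV uncertainty.

    Each cell is drawn independently from a lognormal with mean equal to the
    cell density and coefficient of variation equal to the cell CV
    (mean-preserving parameterization: sigma^2 = ln(1 + cv^2),
    mu = ln D - sigma^2 / 2).  Cells with cv = 0 or zero density pass
    through unchanged.
    """
    d = grid.density
    cv = grid.cv
    out = d.copy()
    mask = (cv > 0) & (d > 0)
    if np.any(mask):
        sigma2 = np.log1p(cv[mask] ** 2)
        mu = np.log(d[mask]) - sigma2 / 2.0
        out[mask] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    return DensityGrid(grid.x_km.copy(), grid.y_km.copy(), out, cv.copy())


def abundance(grid: DensityGrid) -> float:
    """Total number of animals implied by the surface: sum of density x cell area."""
    return float(np.sum(grid.density) * grid.cell_area_km2)


def make_uniform_disc_fixture(
    radius_km: float = 100.0,
    depth_m: float = 50.0,
    cell_km: float = 5.0,
    density_per_km2: float = 0.05,
    cv: float = 0.3,
) -> tuple[DensityGrid, Bathymetry]:
    """The idealized study environment: a uniform density disc over a flat sea.

    Density is constant inside a source-centred disc of the given radius and
    zero outside; bathymetry is flat at ``depth_m`` everywhere.  Output is
    deterministic given the arguments.
    """
    if radius_km <= 0 or depth_m <= 0 or cell_km <= 0:
        raise ValueError("radius, depth and cell size must be positive")
    if density_per_km2 <= 0 or cv < 0:
        raise ValueError("density must be positive and cv nonnegative")
    half_extent = np.ceil(radius_km / cell_km) * cell_km
    ax = np.arange(-half_extent, half_extent + cell_km / 2, cell_km)
    xx, yy = np.meshgrid(ax, ax)
    inside = np.hypot(xx, yy) <= radius_km
    dens = np.where(inside, density_per_km2, 0.0)
    cvs = np.where(inside, cv, 0.0)
    grid = DensityGrid(ax.copy(), ax.copy(), dens, cvs)
    bathy = Bathymetry(ax.copy(), ax.copy(), np.full_like(dens, depth_m))
    return grid, bathy
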