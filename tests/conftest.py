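import numpy as np
import pytest

import exposim as ex
from exposim.scenarios import default_config, default_environment


@pytest.fixture(scope="session")
def species_map():
    return ex.load_packaged_species()


@pytest.fixture(scope="session")
def gray_seal(species_map):
    return species_map["gray seal"]


@pytest.fixture(scope="session")
def porpoise(species_map):
    return species_map["harbor porpoise"]


@pytest.fixture(scope="session")
def disc_env():
    """The idealized stage: uniform 100-km density disc over a flat 50-m sea."""
    return default_environment()


@pytest.fixture(scope="session")
def paper_source():
    return ex.SourceSpec(source_level_db=240.0, frequency_khz=1.0, duty_cycle=0.1)


@pytest.fixture(scope="session")
def log_r15():
    return ex.PropagationModel(k=15.0)


def stationary_profile(gray_seal):
    """A gray-seal-like profile that effectively does not move (1 nm/s)."""
    from dataclasses import replace

    return replace(gray_seal, swim_speed_typical_ms=1e-9, swim_speed_max_ms=1e-9)


@pytest.fixture(scope="session")
def pinned_seal(gray_seal):
    return stationary_profile(gray_seal)


def point_environment(x_km, y_km, depth_m=50.0):
    """An environment whose density collapses onto one (almost) point cell."""
    eps = 1e-6
    ax_x = np.array([x_km, x_km + eps])
    ax_y = np.array([y_km, y_km + eps])
    dens = np.array([[1.0, 0.0], [0.0, 0.0]])
    grid = ex.DensityGrid(ax_x, ax_y, dens, np.zeros_like(dens))
    big = np.linspace(-2000.0, 2000.0, 5)
    bathy = ex.Bathymetry(big, big, np.full((5, 5), depth_m))
    return ex.Environment(grid, bathy)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


__all__ = ["default_config", "point_environment", "stationary_profile"]
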