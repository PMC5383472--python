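"""Directed random walk, aversion, dive cycle, and boundary/land constraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exposim as ex
from exposim.movement import wrap_angle


def make_state(n, x=50.0, y=0.0, rng=None, profile=None):
    rng = rng or np.random.default_rng(0)
    pos = np.column_stack([np.full(n, float(x)), np.full(n, float(y))])
    if profile is None:
        profile = ex.load_packaged_species()["gray seal"]
    return ex.AgentState.initialize(pos, profile, rng)


class TestDrawHeading:
    def test_zero_sd_is_deterministic(self, rng):
        h = ex.draw_heading(np.full(100, 0.7), 0.0, rng)
        np.testing.assert_array_equal(h, np.full(100, 0.7))

    def test_large_sd_is_effectively_uniform(self, rng):
        h = ex.draw_heading(np.zeros(10_000), 10.0, rng)
        rho = np.abs(np.mean(np.exp(1j * h)))
        assert rho <= 0.05  # closed form: e^(-50) ~ 2e-22

    def test_mean_resultant_length_matches_wrapped_normal(self, rng):
        # rho = exp(-sigma^2/2) = exp(-0.125) ~ 0.8825 for sigma = 0.5
        h = ex.draw_heading(np.zeros(10_000), 0.5, rng)
        rho = np.abs(np.mean(np.exp(1j * h)))
        assert rho == pytest.approx(np.exp(-0.125), abs=0.01)

    def test_output_wrapped_to_principal_interval(self, rng):
        h = ex.draw_heading(np.full(1000, 3.0), 5.0, rng)
        assert np.all((h >= -np.pi) & (h < np.pi))

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            ex.draw_heading(0.0, -1.0, rng)


class TestStepAgent:
    def test_displacement_is_speed_times_dt(self, rng):
        state = make_state(1, x=10.0, y=0.0)
        x0, y0 = state.x_km.copy(), state.y_km.copy()
        params = ex.MovementParams(speed_ms=1.5, heading_sd=0.3)
        ex.step_agent(state, params, 60.0, (0.0, 0.0), rng=rng)
        d_km = np.hypot(state.x_km - x0, state.y_km - y0)
        assert d_km == pytest.approx(0.09)  # 1.5 m/s * 60 s = 90 m

    def test_strong_aversion_is_radial_flight(self, rng):
        # 1000 steps of directed fleeing: net range gain ~ speed * time
        state = make_state(200, x=20.0, y=0.0)
        params = ex.MovementParams(speed_ms=1.5, heading_sd=0.05, aversive=True)
        for _ in range(1000):
            ex.step_agent(state, params, 60.0, (0.0, 0.0), rng=rng)
        r = np.hypot(state.x_km, state.y_km)
        expected = 20.0 + 1.5 * 1000 * 60.0 / 1000.0  # 110 km
        assert np.mean(r) == pytest.approx(expected, rel=0.02)

    def test_directionless_walk_is_diffusive(self, rng):
        # uniform headings: E|net| ~ step * sqrt(pi n)/2 << speed * t
        n_steps, step_km = 400, 0.09
        state = make_state(600, x=0.0, y=0.0)
        params = ex.MovementParams(speed_ms=1.5, heading_sd=10.0)
        for _ in range(n_steps):
            ex.step_agent(state, params, 60.0, (1e6, 1e6), rng=rng)
        net = np.hypot(state.x_km, state.y_km)
        expected = step_km * np.sqrt(np.pi * n_steps) / 2.0
        assert np.mean(net) == pytest.approx(expected, rel=0.1)
        assert np.mean(net) < 0.15 * step_km * n_steps

    def test_zero_sd_keeps_constant_heading(self, rng):
        state = make_state(5)
        params = ex.MovementParams(speed_ms=1.0, heading_sd=0.0)
        h0 = state.heading.copy()
        for _ in range(50):
            ex.step_agent(state, params, 60.0, (0.0, 0.0), rng=rng)
        np.testing.assert_allclose(state.heading, h0, atol=1e-12)

    def test_headings_uniform_under_large_sd(self, rng):
        # Rayleigh test of circular uniformity, n = 10^4, alpha = 0.01
        state = make_state(10_000)
        params = ex.MovementParams(speed_ms=1.0, heading_sd=10.0)
        ex.step_agent(state, params, 60.0, (0.0, 0.0), rng=rng)
        n = state.n
        rho = np.abs(np.mean(np.exp(1j * state.heading)))
        z = n * rho**2  # Rayleigh statistic; p ~ exp(-z)
        assert np.exp(-z) > 0.01


class TestConstraints:
    def test_specular_reflection_at_hard_radius(self):
        bound = ex.DomainBoundary(radius_km=100.0)
        x, y = ex.apply_constraints(110.0, 0.0, boundary=bound)
        assert (x, y) == pytest.approx((90.0, 0.0))

    def test_bearing_preserved_on_reflection(self):
        bound = ex.DomainBoundary(radius_km=100.0)
        x, y = ex.apply_constraints(77.78, 77.78, boundary=bound)  # r ~ 110 at 45 deg
        assert np.arctan2(y, x) == pytest.approx(np.pi / 4)
        assert np.hypot(x, y) == pytest.approx(2 * 100.0 - np.hypot(77.78, 77.78))

    def test_legal_proposal_unchanged(self):
        bound = ex.DomainBoundary(radius_km=100.0)
        x, y = ex.apply_constraints(30.0, -40.0, boundary=bound)
        assert (x, y) == (30.0, -40.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        r0=st.floats(0.0, 99.0),
        bearing=st.floats(-np.pi, np.pi),
        step=st.floats(0.0, 50.0),
        theta=st.floats(-np.pi, np.pi),
    )
    def test_reflection_never_escapes_boundary(self, r0, bearing, step, theta):
        bound = ex.DomainBoundary(radius_km=100.0)
        x0, y0 = r0 * np.cos(bearing), r0 * np.sin(bearing)
        x, y = ex.apply_constraints(
            x0 + step * np.cos(theta), y0 + step * np.sin(theta), boundary=bound
        )
        assert np.hypot(x, y) <= 100.0 + 1e-9

    def test_land_reverts_to_previous_position(self):
        ax = np.array([0.0, 10.0])
        bathy = ex.Bathymetry(ax, ax, np.array([[50.0, -5.0], [50.0, 50.0]]))
        x, y = ex.apply_constraints(9.0, 1.0, bathymetry=bathy, prev_x_km=1.0, prev_y_km=1.0)
        assert (x, y) == (1.0, 1.0)

    def test_agents_never_breach_constraints_over_many_steps(self, rng):
        # long-run invariant: position always inside the hard radius
        state = make_state(200, x=90.0, y=0.0)
        params = ex.MovementParams(speed_ms=3.0, heading_sd=10.0)
        bound = ex.DomainBoundary(radius_km=100.0)
        ax = np.linspace(-150, 150, 7)
        bathy = ex.Bathymetry(ax, ax, np.full((7, 7), 50.0))
        for _ in range(500):
            ex.step_agent(state, params, 60.0, (0.0, 0.0), bathy, bound, rng)
            assert np.all(np.hypot(state.x_km, state.y_km) <= 100.0 + 1e-9)


class TestDiveCycle:
    def test_depth_capped_by_bathymetry(self, gray_seal, rng):
        # seafloor at 50 m, species max dive 300 m: depth never exceeds 50
        state = make_state(100, profile=gray_seal)
        ax = np.linspace(-200, 200, 5)
        bathy = ex.Bathymetry(ax, ax, np.full((5, 5), 50.0))
        for _ in range(300):
            d = ex.dive_depth(state, gray_seal, 60.0, bathy, rng)
            assert np.all((d >= 0.0) & (d <= 50.0))

    def test_surface_phase_is_at_zero_depth(self, gray_seal, rng):
        state = make_state(1, profile=gray_seal)
        state.dive_phase_s = np.array([gray_seal.typical_dive_duration_s + 1.0])
        ax = np.linspace(-200, 200, 5)
        bathy = ex.Bathymetry(ax, ax, np.full((5, 5), 500.0))
        d = ex.dive_depth(state, gray_seal, 10.0, bathy, rng)
        assert d[0] == 0.0

    def test_mean_cycle_length(self, gray_seal, rng):
        # count surfacing events over a long run: cycle ~ dive + surface time
        state = make_state(50, profile=gray_seal)
        ax = np.linspace(-200, 200, 5)
        bathy = ex.Bathymetry(ax, ax, np.full((5, 5), 500.0))
        dt, n_steps = 30.0, 4000
        submerged_prev = np.zeros(50, dtype=bool)
        dives = np.zeros(50)
        for _ in range(n_steps):
            d = ex.dive_depth(state, gray_seal, dt, bathy, rng)
            submerged = d > 0
            dives += (~submerged_prev) & submerged
            submerged_prev = submerged
        cycle = gray_seal.typical_dive_duration_s + gray_seal.surface_time_s
        observed = dt * n_steps / np.mean(dives)
        assert observed == pytest.approx(cycle, rel=0.1)


@settings(derandomize=True, max_examples=200)
@given(st.floats(-50.0, 50.0))
def test_wrap_angle_principal_interval(theta):
    w = wrap_angle(theta)
    assert -np.pi <= w < np.pi
    assert np.cos(w) == pytest.approx(np.cos(theta), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(theta), abs=1e-9)
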