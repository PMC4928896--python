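"""Solver behaviour: conservation, fixed points, convergence, invariances."""

import numpy as np
import pytest

from myxospread import (
    ConfigurationError,
    FieldState,
    ModelParameters,
    NumericalError,
    RadialGrid,
    initial_state,
    simulate,
    step,
)
from myxospread.pde_solver import _clip_field
from myxospread.wavefront import front_trajectory, steady_state_speed


def small_params(**kw):
    defaults = dict(r0=1000.0, rb=4000.0, DN=0.0, rho_edge=1.0)
    defaults.update(kw)
    return ModelParameters(**defaults)


class TestGridAndInitialState:
    def test_grid_geometry(self):
        g = RadialGrid(1000.0, 4000.0, 301)
        assert g.dx == pytest.approx(10.0)
        assert g.nodes[0] == 1000.0 and g.nodes[-1] == 4000.0
        assert g.volumes.sum() == pytest.approx((4000.0**2 - 1000.0**2) / 2)

    def test_grid_validation(self):
        with pytest.raises(ConfigurationError):
            RadialGrid(1000.0, 4000.0, 2)
        with pytest.raises(ConfigurationError):
            RadialGrid(4000.0, 1000.0, 10)

    @pytest.mark.parametrize("n", [3, 101])
    def test_initial_state_uniform(self, n):
        p = small_params()
        g = RadialGrid(p.r0, p.rb, n)
        s = initial_state(p, g)
        assert s.t == 0.0
        assert np.all(s.rho == 0.0) and np.all(s.e == 0.0)
        assert np.all(s.N == p.Nin)

    def test_initial_state_geometry_mismatch(self):
        p = small_params()
        with pytest.raises(ConfigurationError):
            initial_state(p, RadialGrid(p.r0, p.rb + 1.0, 11))

    def test_negligible_nutrients_frozen_colony(self):
        # Monod(0) = 0: with vanishing nutrients nothing grows
        p = small_params(Nin=1e-12, c0=0.0)
        g = RadialGrid.for_params(p, dx=100.0)
        res = simulate(p, g, t_end=600.0, dt=1.0)
        assert np.all(res.snapshots[-1].rho == 0.0)


class TestStep:
    def test_mass_conserved_without_reactions(self):
        p = small_params(gmax=0.0, alpha=0.0, c0=0.0, Dp=0.0)
        g = RadialGrid.for_params(p, dx=30.0)
        s = initial_state(p, g)
        s.rho = np.exp(-(((g.nodes - 2000.0) / 300.0) ** 2))
        mass0 = np.dot(g.volumes, s.rho)
        for _ in range(1000):
            s = step(s, p, g, 0.5)
        assert abs(np.dot(g.volumes, s.rho) - mass0) / mass0 < 1e-8

    def test_empty_colony_is_fixed_point(self):
        p = small_params(c0=0.0)
        g = RadialGrid.for_params(p, dx=100.0)
        res = simulate(p, g, t_end=600.0, dt=1.0)
        final = res.snapshots[-1]
        assert np.all(final.rho == 0.0) and np.all(final.e == 0.0)
        assert np.allclose(final.N, p.Nin, rtol=1e-12)

    def test_nutrient_bookkeeping_is_exact(self):
        # growth converts nutrient to density 1:1; with c0=0 the total
        # integral of rho+N changes only through boundary fluxes (none)
        p = small_params(DN=1.0e4, c0=0.0)
        g = RadialGrid.for_params(p, dx=30.0)
        s = initial_state(p, g)
        s.rho = 0.5 * np.exp(-(((g.nodes - 1500.0) / 200.0) ** 2))
        total0 = np.dot(g.volumes, s.rho + s.N)
        for _ in range(500):
            s = step(s, p, g, 1.0)
        total1 = np.dot(g.volumes, s.rho + s.N)
        assert abs(total1 - total0) / total0 < 1e-6
        assert np.dot(g.volumes, s.rho) > 1.05 * 0.5  # growth actually happened

    def test_dt_must_be_positive(self):
        p = small_params()
        g = RadialGrid.for_params(p, dx=100.0)
        with pytest.raises(ValueError):
            step(initial_state(p, g), p, g, 0.0)

    def test_clip_rejects_large_negatives(self):
        arr = np.array([0.5, -1.0e-3, 0.2])
        with pytest.raises(NumericalError, match="rho"):
            _clip_field(arr, "rho", 10.0, 1e-8)
        arr2 = np.array([0.5, -1.0e-10, 0.2])
        _clip_field(arr2, "rho", 10.0, 1e-8)
        assert arr2[1] == 0.0


class TestSimulate:
    def test_zero_duration_returns_initial(self):
        p = small_params()
        g = RadialGrid.for_params(p, dx=100.0)
        res = simulate(p, g, t_end=0.0, dt=1.0)
        assert len(res.snapshots) == 1
        assert np.all(res.snapshots[0].N == p.Nin)

    def test_deterministic_bit_identical(self):
        p = small_params()
        g = RadialGrid.for_params(p, dx=60.0)
        r1 = simulate(p, g, t_end=300.0, output_times=[150.0, 300.0], dt=1.0)
        r2 = simulate(p, g, t_end=300.0, output_times=[150.0, 300.0], dt=1.0)
        for a, b in zip(r1.snapshots, r2.snapshots):
            assert np.array_equal(a.rho, b.rho)
            assert np.array_equal(a.N, b.N)
            assert np.array_equal(a.e, b.e)

    def test_snapshot_times_increasing_first_is_initial(self):
        p = small_params()
        g = RadialGrid.for_params(p, dx=60.0)
        res = simulate(p, g, t_end=200.0, output_times=[50.0, 100.0, 200.0], dt=1.0)
        times = res.times
        assert times[0] == 0.0
        assert np.all(np.diff(times) > 0)

    def test_output_times_outside_range_rejected(self):
        p = small_params()
        g = RadialGrid.for_params(p, dx=100.0)
        with pytest.raises(ValueError):
            simulate(p, g, t_end=100.0, output_times=[200.0], dt=1.0)

    def test_accuracy_guard_warns(self):
        p = small_params(DN=1.0e4)
        g = RadialGrid.for_params(p, dx=10.0)
        with pytest.warns(UserWarning, match="diffusion number"):
            simulate(p, g, t_end=2.0, dt=1.0)

    def test_front_advances_monotonically(self, soft_agar_dn0):
        p = soft_agar_dn0.evolve(rb=1700.0 + 3000.0)
        g = RadialGrid.for_params(p, dx=30.0)
        res = simulate(p, g, t_end=30 * 60.0, output_times=list(np.arange(0, 1801, 120.0)), dt=1.0)
        radii = front_trajectory(res).front_radius
        assert np.all(np.diff(radii) >= 0)

    def test_grid_and_dt_convergence_of_front_speed(self, soft_agar_dn0):
        # halving dx and dt moves the measured speed by < 2%
        p = soft_agar_dn0.evolve(rb=1700.0 + 4000.0)
        speeds = []
        for dx, dt in [(20.0, 1.0), (10.0, 0.5)]:
            g = RadialGrid.for_params(p, dx=dx)
            res = simulate(
                p, g, t_end=45 * 60.0, output_times=list(np.arange(0, 45 * 60.0 + 1, 60.0)), dt=dt
            )
            speed, _, _ = steady_state_speed(front_trajectory(res))
            speeds.append(speed)
        assert abs(speeds[1] - speeds[0]) / speeds[1] < 0.02

    def test_comparison_principle_in_nutrients(self):
        # more initial nutrients never yields less density anywhere/anytime
        base = small_params(rb=2500.0)
        rich = base.evolve(Nin=4.0)
        out = {}
        for tag, p in [("base", base), ("rich", rich)]:
            g = RadialGrid.for_params(p, dx=50.0)
            out[tag] = simulate(
                p, g, t_end=20 * 60.0, output_times=[300.0, 600.0, 1200.0], dt=1.0
            )
        for a, b in zip(out["base"].snapshots, out["rich"].snapshots):
            assert np.all(b.rho >= a.rho - 1e-10)

    def test_eps_slaves_to_local_density(self, soft_agar_dn0):
        # behind the front e tracks alpha*rho/beta closely
        p = soft_agar_dn0.evolve(rb=1700.0 + 3000.0)
        g = RadialGrid.for_params(p, dx=30.0)
        res = simulate(p, g, t_end=30 * 60.0, dt=1.0)
        s = res.snapshots[-1]
        from myxospread.wavefront import front_position

        edge = front_position(s, g, 0.01)
        interior = (s.rho > 1.0) & (g.nodes < edge - 600.0)  # behind the rise zone
        e_star = p.alpha * s.rho[interior] / p.beta
        assert interior.sum() > 10
        assert np.all(np.abs(s.e[interior] - e_star) / e_star < 0.02)

    def test_eps_rescaling_invariance(self):
        # (e0=k, alpha) is (e0=1, alpha/k) with the EPS axis rescaled by k
        k = 2.5
        p1 = small_params(rb=2500.0, e0=1.0)
        pk = p1.evolve(e0=k, alpha=p1.alpha * k)
        g = RadialGrid.for_params(p1, dx=50.0)
        r1 = simulate(p1, g, t_end=600.0, dt=1.0)
        rk = simulate(pk, g, t_end=600.0, dt=1.0)
        s1, sk = r1.snapshots[-1], rk.snapshots[-1]
        assert np.allclose(sk.rho, s1.rho, rtol=1e-10, atol=1e-12)
        assert np.allclose(sk.N, s1.N, rtol=1e-10, atol=1e-12)
        assert np.allclose(sk.e, k * s1.e, rtol=1e-10, atol=1e-12)


def test_field_state_validation_catches_bad_values():
    s = FieldState(0.0, np.array([0.0, np.nan]), np.zeros(2), np.zeros(2))
    with pytest.raises(NumericalError, match="rho"):
        s.validate()
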