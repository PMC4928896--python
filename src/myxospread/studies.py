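"""End-to-end study drivers: the standard numerical experiments of the model.

Each function runs one self-contained study (traveling-wave emergence,
PDE vs phase-space speed comparison, speed-scaling sweeps, nutrient
dependence, density-dependent lag, Hill-coefficient sensitivity, parameter
recovery) at documented problem sizes and returns a dict of measured
quantities.  The pytest acceptance suite asserts on these results and
``scripts/acceptance.py`` serialises them.

Problem sizes (grid spacing, time step, horizons, ladder sizes) are chosen
so each study resolves the quantity it measures — see docs/methods.md for
the convergence checks behind the defaults.
"""

from __future__ import annotations

import numpy as np

from .calibration import (
    density_sweep,
    density_to_rho_init,
    fit_parameters,
    generate_synthetic_assay,
)
from .core_model import (
    MIN_PER_HOUR,
    ModelParameters,
    estimate_Dp_from_motility,
    growth_rate_from_doubling,
)
from .pde_solver import RadialGrid, simulate
from .phase_space import (
    c_max,
    c_min,
    extended_fisher_speed,
    reference_speed_cprime,
    wave_speed_phase_space,
)
from .wavefront import analyze_front, front_trajectory, front_width, steady_state_speed

__all__ = [
    "soft_agar_params",
    "motility_parameter_estimates",
    "traveling_wave_emergence",
    "pde_vs_phase_space",
    "speed_scaling",
    "nutrient_speed_sweep",
    "lag_density_sweep",
    "hill_threshold_study",
    "parameter_recovery_study",
]

#: assay cell ladder used by the lag study (100-fold range plus a 2x top pair)
LAG_LADDER_CELLS = (6e4, 3e5, 1.5e6, 6e6, 1.2e7)


def soft_agar_params(**overrides) -> ModelParameters:
    """The soft-agar (0.5%) parameter set, rates converted from per-hour."""
    return ModelParameters.with_hour_rates(gmax=0.173, alpha=19.0, beta=16.0).evolve(**overrides)


def motility_parameter_estimates() -> dict:
    """Analytic single-cell parameter reproductions (no simulation)."""
    return {
        "Dp_estimate_low_um2_min": estimate_Dp_from_motility(vg=4.0, f=0.1),
        "Dp_estimate_high_um2_min": estimate_Dp_from_motility(vg=7.0, f=0.1),
        "growth_rate_per_h": growth_rate_from_doubling(4.0),
    }


def traveling_wave_emergence(
    t_end_h: float = 150.0,
    dx: float = 20.0,
    dt: float = 0.5,
    sample_every_h: float = 4.0,
) -> dict:
    """Long soft-agar run (diffusing nutrients, full 30-mm domain).

    Measures the late-time front speed, its coefficient of variation over
    the final 20% of the run, and the constancy of the front width (rise of
    the profile between 0.1*Nin and 0.9*Nin) across late snapshots.
    """
    params = soft_agar_params()
    grid = RadialGrid.for_params(params, dx=dx)
    t_end = t_end_h * MIN_PER_HOUR
    times = list(np.arange(0.0, t_end + 1e-9, sample_every_h * MIN_PER_HOUR))
    result = simulate(params, grid, t_end=t_end, output_times=times, dt=dt)
    traj = front_trajectory(result)
    rates = np.diff(traj.front_radius) / np.diff(traj.times)
    late = rates[int(round(0.8 * rates.size)):]
    n_late = max(2, int(round(0.2 * len(result.snapshots))))
    widths = np.array(
        [
            front_width(s, grid, 0.1 * params.Nin, 0.9 * params.Nin)
            for s in result.snapshots[-n_late:]
        ]
    )
    step_changes = np.abs(np.diff(widths)) / widths[:-1] * 100.0
    return {
        "steady_speed_um_min": float(late.mean()),
        "late_speed_cv_pct": float(late.std() / late.mean() * 100.0),
        "front_width_um": float(widths.mean()),
        # shape constancy between consecutive equidistant late snapshots;
        # the window-wide spread is kept as a diagnostic of the slow
        # sqrt(DN t) widening transient (see docs/methods.md)
        "front_width_max_step_change_pct": float(step_changes.max()),
        "front_width_spread_pct": float((widths.max() - widths.min()) / widths.mean() * 100.0),
        "front_advance_mm": float((traj.front_radius[-1] - params.r0) / 1000.0),
        "n": grid.n,
    }


def pde_vs_phase_space(
    t_end_h: float = 150.0,
    dx: float = 20.0,
    dt: float = 0.5,
) -> dict:
    """Front-speed agreement for non-diffusing nutrients.

    Full nonlinear-diffusion case: PDE steady speed vs the shooting speed.
    Constant-diffusion control (Dp = 0): both vs the closed form
    2 sqrt(D0 gmax Nin/(N0+Nin)); the Dp = 0 PDE run uses a finer grid
    because the basal-diffusion front is only ~15 um wide.
    """
    params = soft_agar_params(DN=0.0, rb=1700.0 + 12000.0)
    grid = RadialGrid.for_params(params, dx=dx)
    t_end = t_end_h * MIN_PER_HOUR
    times = list(np.arange(0.0, t_end + 1e-9, 4.0 * MIN_PER_HOUR))
    res = simulate(params, grid, t_end=t_end, output_times=times, dt=dt)
    pde_speed, _, _ = steady_state_speed(front_trajectory(res))
    shooting = wave_speed_phase_space(params)

    flat = params.evolve(Dp=0.0, rb=1700.0 + 2500.0)
    grid0 = RadialGrid.for_params(flat, dx=10.0)
    res0 = simulate(flat, grid0, t_end=t_end, output_times=times, dt=1.0)
    pde_flat, _, _ = steady_state_speed(front_trajectory(res0))
    closed = extended_fisher_speed(flat.D0, flat.gmax, flat.Nin, flat.N0)
    shoot_flat = wave_speed_phase_space(flat)
    return {
        "pde_speed_um_min": float(pde_speed),
        "phase_space_speed_um_min": float(shooting.c),
        "pde_phase_space_rel_diff_pct": float(abs(pde_speed / shooting.c - 1.0) * 100.0),
        "const_D_closed_form_um_min": float(closed),
        "const_D_pde_rel_diff_pct": float(abs(pde_flat / closed - 1.0) * 100.0),
        "const_D_shooting_rel_diff_pct": float(abs(shoot_flat.c / closed - 1.0) * 100.0),
        "n": grid.n,
    }


def speed_scaling() -> dict:
    """Fisher-like square-root scaling: 4x in Dp or gmax doubles the speed."""
    base = soft_agar_params(D0=0.5, Dp=64.0, DN=0.0)
    c_base = wave_speed_phase_space(base).c
    c_dp = wave_speed_phase_space(base.evolve(Dp=4 * base.Dp)).c
    c_g = wave_speed_phase_space(base.evolve(gmax=4 * base.gmax)).c
    return {
        "speed_ratio_Dp_x4": float(c_dp / c_base),
        "speed_ratio_gmax_x4": float(c_g / c_base),
        "n": 3,
    }


def nutrient_speed_sweep(nin_values=(0.3, 0.55, 1.0, 1.8, 3.0)) -> dict:
    """Wave speed vs initial nutrient level, with the closed-form bounds."""
    params = soft_agar_params(DN=0.0)
    speeds, in_bounds, cprime_in = [], 0, 0
    for nin in nin_values:
        p = params.evolve(Nin=float(nin))
        c = wave_speed_phase_space(p).c
        speeds.append(c)
        if c_min(p) - 1e-9 <= c <= c_max(p) + 1e-9:
            in_bounds += 1
        if c_min(p) <= reference_speed_cprime(p) <= c_max(p):
            cprime_in += 1
    speeds = np.asarray(speeds)
    return {
        "speed_at_lowest_Nin_um_min": float(speeds[0]),
        "speed_at_highest_Nin_um_min": float(speeds[-1]),
        "monotonicity_violations": int(np.sum(np.diff(speeds) < -1e-9)),
        "outside_bounds_count": int(len(speeds) - in_bounds),
        "cprime_outside_bounds_count": int(len(speeds) - cprime_in),
        "speeds": speeds,
        "n": len(speeds),
    }


def lag_density_sweep(
    cells_per_spot=LAG_LADDER_CELLS,
    t_end_h: float = 120.0,
    dx: float = 20.0,
    dt: float = 1.0,
    sample_every_min: float = 30.0,
) -> dict:
    """Density-dependent lag phase and density-independent steady speed.

    Non-diffusing nutrients isolate the EPS-gating lag mechanism from the
    slow global nutrient-depletion transient (see docs/methods.md); the
    ladder spans 100-fold in cell number with a 2x pair at the top.
    """
    params = soft_agar_params(DN=0.0, rb=1700.0 + 10000.0)
    lags, speeds = [], []
    t_end = t_end_h * MIN_PER_HOUR
    times = list(np.arange(0.0, t_end + 1e-9, sample_every_min))
    for cells in cells_per_spot:
        rho0 = density_to_rho_init(float(cells), params.r0, "monolayer")
        p = params.evolve(rho_edge=rho0)
        grid = RadialGrid.for_params(p, dx=dx)
        res = simulate(p, grid, t_end=t_end, output_times=times, dt=dt)
        summary = analyze_front(front_trajectory(res))
        lags.append(summary.lag_duration / MIN_PER_HOUR)
        speeds.append(summary.steady_speed)
    lags = np.asarray(lags)
    speeds = np.asarray(speeds)
    top_small, top_large = sorted(lags[-2:])
    return {
        "lag_lowest_density_h": float(lags[0]),
        "lag_highest_density_h": float(lags[-1]),
        "lag_ordering_violations": int(np.sum(np.diff(lags) > 1e-9)),
        "steady_speed_spread_pct": float((speeds.max() - speeds.min()) / speeds.min() * 100.0),
        "top_pair_lag_diff_pct": float(
            0.0 if top_large == top_small == 0.0 else (top_large - top_small) / max(top_small, 1e-9) * 100.0
        ),
        "lags_h": lags,
        "speeds_um_min": speeds,
        "n": len(lags),
    }


def hill_threshold_study(
    n_densities: int = 8,
    t_final_h: float = 24.0,
    dx: float = 25.0,
    dt: float = 1.5,
) -> dict:
    """Necessity of a sharp (high Hill coefficient) EPS gate.

    Noise-free endpoint data are generated at m = 4 and refit over
    {Dp, alpha} with m fixed at 1 and at 4.  The m = 1 family cannot
    reproduce the sharp density threshold: its best SSE stays far above the
    m = 4 fit, and its radius-vs-log-density curve has a much smaller
    maximum second difference.
    """
    true = soft_agar_params(DN=0.0, rb=1700.0 + 2600.0)
    cells = tuple(np.geomspace(6e4, 1.2e7, n_densities))
    data = generate_synthetic_assay(
        true, cells_per_spot=cells, sample_times_h=(t_final_h,), noise_sigma=0.0,
        seed=0, dx=dx, dt=dt,
    )
    fits = {}
    for m in (4.0, 1.0):
        fits[m] = fit_parameters(
            data, true.evolve(m=m), free=("Dp", "alpha"), grid_points=4,
            dx=dx, dt=dt, maxiter=30,
        )

    def sharpness(params):
        dens = [density_to_rho_init(c, true.r0, "monolayer") for c in cells]
        table = density_sweep(params, dens, t_final_h, dx=dx, dt=dt)
        y = table["radius_increase_um"].to_numpy()
        x = np.log(np.asarray(dens))
        return float(np.max(np.abs(np.diff(y, 2))) / np.diff(x)[0] ** 2)

    sharp_m4 = sharpness(true)
    sharp_m1 = sharpness(fits[1.0].full_params)
    return {
        "sse_m1": float(fits[1.0].sse),
        "sse_m4": float(fits[4.0].sse),
        "sse_ratio_m1_over_m4": float(fits[1.0].sse / max(fits[4.0].sse, 1e-12)),
        "sharpness_ratio_m4_over_m1": float(sharp_m4 / sharp_m1),
        "n": len(data.data),
    }


def parameter_recovery_study(
    seed: int = 1,
    n_seeds: int = 3,
    noise_sigma: float = 100.0,
    dx: float = 25.0,
    dt: float = 1.5,
) -> dict:
    """Recovery of {Dp, alpha} from noisy synthetic time-course assays.

    One dataset per seed (three densities, 6-48 h time course, sigma = 100
    um measurement noise), each refit from scratch.
    """
    true = soft_agar_params(DN=0.0, rb=1700.0 + 3600.0)
    cells = (3e5, 1.5e6, 1.2e7)
    times = tuple(float(t) for t in range(6, 49, 6))
    dp_errs, alpha_errs = [], []
    for k in range(n_seeds):
        data = generate_synthetic_assay(
            true, cells_per_spot=cells, sample_times_h=times,
            noise_sigma=noise_sigma, seed=int(seed) + k, dx=dx, dt=dt,
        )
        fit = fit_parameters(
            data, true, free=("Dp", "alpha"), grid_points=4, dx=dx, dt=dt, maxiter=40,
        )
        dp_errs.append(abs(fit.params["Dp"] / true.Dp - 1.0) * 100.0)
        alpha_errs.append(abs(fit.params["alpha"] / true.alpha - 1.0) * 100.0)
    return {
        "Dp_recovery_worst_rel_err_pct": float(max(dp_errs)),
        "alpha_recovery_worst_rel_err_pct": float(max(alpha_errs)),
        "Dp_recovery_mean_rel_err_pct": float(np.mean(dp_errs)),
        "alpha_recovery_mean_rel_err_pct": float(np.mean(alpha_errs)),
        "n": n_seeds,
    }
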