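"""Traveling-wave speeds: closed forms and the phase-space shooting solver.

With the EPS field slaved to its local steady state e* = alpha*rho/beta the
model reduces to two fields.  In the co-moving coordinate z = x - c*t the
traveling-wave profile satisfies a first-order autonomous system,

    rho'(z)   = [ -c (rho + N - Nin) + DN * Omega ] / D(rho)
    N'(z)     = Omega
    Omega'(z) = [ rho gmax N/(N0+N) - c Omega ] / DN

where D(rho) = D0 + Dp*phi(alpha*rho/beta) and the integration constant of
the first integral, -c*Nin, is fixed by the unpopulated state ahead of the
front.  A front is a heteroclinic orbit from the saddle (Nin, 0, 0) (behind
the wave) to the stable node (0, Nin, 0) (ahead of it).  As c increases the
orbit's cell-density component transitions from oscillatory, to negative in
a single excursion, to non-negative; the selected wave speed is the minimal
c with a non-negative orbit, found by bisection.

For non-diffusing nutrients (DN = 0) the N equation degenerates; the
explicit two-variable reduction

    rho'(z) = -c (rho + N - Nin) / D(rho)
    N'(z)   = gmax rho N / ((N0 + N) c)

is used instead.  The constant-diffusion benchmark is the nutrient-extended
Fisher speed c = 2 sqrt(D gmax Nin/(N0+Nin)).

The selection criterion (and hence :func:`wave_speed_phase_space`) is only
meaningful for DN = 0: with diffusing nutrients the leading-edge fixed
point has a two-dimensional unstable manifold in z, forward-shot orbits
escape along the slow nutrient mode whatever the speed, and the label
progression breaks down.  Front speeds with DN > 0 are measured from the
PDE solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import ModelParameters, hill_phi
from .exceptions import NumericalError

__all__ = [
    "PhasePoint",
    "WaveSpeedResult",
    "fisher_speed",
    "extended_fisher_speed",
    "c_min",
    "c_max",
    "reference_speed_cprime",
    "slaved_diffusion",
    "reduced_rhs",
    "classify_trajectory",
    "wave_speed_phase_space",
]


@dataclass(frozen=True)
class PhasePoint:
    """A point (rho, N, Omega) of the reduced co-moving system; Omega = dN/dz."""

    rho: float
    N: float
    Omega: float = 0.0


@dataclass
class WaveSpeedResult:
    c: float                       # um/min
    classification_log: list = field(default_factory=list)  # (c, label) pairs
    bisection_tol: float = 0.0
    converged: bool = False
    c_min: float = 0.0
    c_max: float = 0.0


def fisher_speed(D: float, g: float) -> float:
    """Fisher-KPP pulled-front speed c = 2 sqrt(D g)."""
    if D < 0 or g < 0:
        raise ValueError("D and g must be >= 0")
    return 2.0 * math.sqrt(D * g)


def extended_fisher_speed(D: float, gmax: float, Nin: float, N0: float) -> float:
    """Front speed with Monod growth and non-diffusing nutrients.

    c = 2 sqrt(D gmax Nin / (N0 + Nin)): the Fisher speed evaluated at the
    growth rate of the wave tip, where nutrients are still at Nin.
    """
    if min(D, gmax, Nin, N0) < 0:
        raise ValueError("all arguments must be >= 0")
    if N0 + Nin <= 0:
        raise ValueError("N0 + Nin must be > 0")
    return 2.0 * math.sqrt(D * gmax * Nin / (N0 + Nin))


def c_min(params: ModelParameters) -> float:
    """Lower speed bound: constant-diffusion front at the basal rate D0."""
    return extended_fisher_speed(params.D0, params.gmax, params.Nin, params.N0)


def c_max(params: ModelParameters) -> float:
    """Upper speed bound: constant-diffusion front at saturated EPS, D0+Dp."""
    return extended_fisher_speed(params.D0 + params.Dp, params.gmax, params.Nin, params.N0)


def reference_speed_cprime(params: ModelParameters) -> float:
    """Speed c' with EPS frozen at half saturation, i.e. D = D0 + Dp/2."""
    return extended_fisher_speed(params.D0 + 0.5 * params.Dp, params.gmax, params.Nin, params.N0)


def slaved_diffusion(rho, params: ModelParameters):
    """D(rho) = D(e*) with the EPS slaved to e* = alpha*rho/beta."""
    if params.beta <= 0:
        raise NumericalError("EPS slaving requires beta > 0")
    e_star = params.alpha * np.maximum(np.asarray(rho, dtype=float), 0.0) / params.beta
    out = params.D0 + params.Dp * hill_phi(e_star, params.e0, params.m)
    return float(out) if np.ndim(rho) == 0 else out


def reduced_rhs(p: PhasePoint, c: float, params: ModelParameters) -> PhasePoint:
    """Right-hand side of the co-moving system at phase point ``p``.

    For DN = 0 the Omega component is unused (the two-variable reduction
    applies); its derivative slot is returned as 0.
    """
    d = slaved_diffusion(p.rho, params)
    if d <= 0:
        raise NumericalError("D(rho) = 0: phase-space equations are singular")
    monod = p.N / (params.N0 + p.N) if p.N > -params.N0 else 0.0
    if params.DN > 0:
        drho = (-c * (p.rho + p.N - params.Nin) + params.DN * p.Omega) / d
        dN = p.Omega
        dOmega = (p.rho * params.gmax * monod - c * p.Omega) / params.DN
        return PhasePoint(drho, dN, dOmega)
    if c <= 0:
        raise NumericalError("the DN = 0 reduction needs c > 0")
    drho = -c * (p.rho + p.N - params.Nin) / d
    dN = params.gmax * p.rho * monod / c
    return PhasePoint(drho, dN, 0.0)


def _saddle_jacobian(c: float, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian at the saddle (rho=Nin, N=0[, Omega=0])."""
    d = slaved_diffusion(params.Nin, params)
    if params.DN > 0:
        return np.array(
            [
                [-c / d, -c / d, params.DN / d],
                [0.0, 0.0, 1.0],
                [0.0, params.Nin * params.gmax / (params.N0 * params.DN), -c / params.DN],
            ]
        )
    return np.array(
        [
            [-c / d, -c / d],
            [0.0, params.gmax * params.Nin / (params.N0 * c)],
        ]
    )


def node_eigenvalues(c: float, params: ModelParameters) -> np.ndarray:
    """Eigenvalues of the linearisation at the stable node (0, Nin[, 0]).

    Complex eigenvalues mean the orbit spirals into the node, i.e. an
    oscillatory density profile; this happens exactly for c < c_min because
    the node linearisation only feels the basal diffusion D(0) = D0.
    """
    d0 = slaved_diffusion(0.0, params)
    b = params.gmax * params.Nin / (params.N0 + params.Nin)
    if params.DN > 0:
        jac = np.array(
            [
                [-c / d0, -c / d0, params.DN / d0],
                [0.0, 0.0, 1.0],
                [b / params.DN, 0.0, -c / params.DN],
            ]
        )
    else:
        jac = np.array([[-c / d0, -c / d0], [b / c, 0.0]])
    return np.linalg.eigvals(jac)


def _unstable_direction(c: float, params: ModelParameters) -> np.ndarray:
    jac = _saddle_jacobian(c, params)
    eigvals, eigvecs = np.linalg.eig(jac)
    unstable = [i for i, lam in enumerate(eigvals) if lam.real > 1e-12 and abs(lam.imag) < 1e-9]
    if len(unstable) != 1:
        raise NumericalError(
            f"expected one unstable direction at the saddle, found {len(unstable)} (c={c})"
        )
    v = eigvecs[:, unstable[0]].real
    if v[1] < 0:  # orient so N grows away from the saddle
        v = -v
    return v / np.linalg.norm(v)


def classify_trajectory(
    c: float,
    params: ModelParameters,
    *,
    z_max: float = 1.0e6,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-12,
    eps_rel: float = 1.0e-6,
    neg_tol_rel: float = 1.0e-9,
    arrive_rel: float = 1.0e-7,
) -> str:
    """Shoot from the saddle and label the orbit's density component.

    Integration starts a distance ``eps_rel * Nin`` from the saddle along
    its unstable eigendirection and runs until the orbit arrives within
    ``arrive_rel`` of the stable node (or ``z_max`` is hit).  The label is

    - ``"oscillatory"``: the orbit spirals into the node so rho changes sign
      repeatedly.  This happens exactly when the node eigenvalues are
      complex, i.e. for c below the basal-diffusion speed bound c_min; the
      eigenvalue criterion is used directly because near the transition the
      oscillation amplitude decays below any integration tolerance, and the
      trajectory's sign changes are kept as a cross-check.
    - ``"negative"``: a single negative excursion of rho below ``-neg_tol``,
    - ``"nonnegative"``: rho stays above ``-neg_tol`` all the way in.

    Only the DN = 0 reduction supports this criterion: with diffusing
    nutrients the leading-edge fixed point acquires a second unstable
    direction in z and the forward-shot orbit escapes along the (slow)
    nutrient mode regardless of whether a front exists, so the labels above
    lose their meaning.  Pass params with DN = 0 (front speeds with
    diffusing nutrients are measured from the PDE solver instead).
    """
    if params.DN > 0:
        raise NumericalError(
            "the non-negativity shooting criterion applies to the DN = 0 "
            "reduction only: with DN > 0 the leading-edge fixed point is not "
            "attracting in z and forward-shot orbits escape along the "
            "nutrient mode; measure DN > 0 front speeds from the PDE solver"
        )
    nin = params.Nin
    neg_tol = neg_tol_rel * nin
    if np.any(np.abs(np.imag(node_eigenvalues(c, params))) > 1e-12):
        return "oscillatory"
    v = _unstable_direction(c, params)
    y0 = np.array([nin, 0.0, 0.0][: v.size]) + eps_rel * nin * v

    def rhs(z, y):
        if y.size == 3:
            p = PhasePoint(y[0], y[1], y[2])
            d = reduced_rhs(p, c, params)
            return [d.rho, d.N, d.Omega]
        p = PhasePoint(y[0], y[1], 0.0)
        d = reduced_rhs(p, c, params)
        return [d.rho, d.N]

    def ev_down(z, y):  # rho crossing below -neg_tol
        return y[0] + neg_tol

    ev_down.terminal = False
    ev_down.direction = -1.0

    def ev_arrive(z, y):  # L1 distance to the node (0, Nin) falls below tolerance
        return abs(nin - y[1]) + abs(y[0]) - arrive_rel * nin

    ev_arrive.terminal = True
    ev_arrive.direction = -1.0

    def ev_deep_negative(z, y):  # orbit escapes far below rho = 0
        return y[0] + 5.0 * nin

    ev_deep_negative.terminal = True
    ev_deep_negative.direction = -1.0

    def ev_blowup(z, y):  # orbit escapes upward: shooting missed the manifold
        return 10.0 * nin - y[0]

    ev_blowup.terminal = True
    ev_blowup.direction = -1.0

    sol = solve_ivp(
        rhs,
        (0.0, z_max),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=[ev_down, ev_arrive, ev_deep_negative, ev_blowup],
        dense_output=False,
    )
    if not sol.success:
        raise NumericalError(f"phase-space integration failed at c={c}: {sol.message}")
    if len(sol.t_events[3]) > 0:
        raise NumericalError(
            f"orbit escaped upward at c={c}; the saddle departure missed the unstable manifold"
        )
    down_crossings = len(sol.t_events[0])
    arrived = len(sol.t_events[1]) > 0
    min_rho = float(np.min(sol.y[0]))

    if down_crossings >= 2:
        return "oscillatory"  # sign-change cross-check; eigenvalues said real
    if down_crossings >= 1 or min_rho < -neg_tol or len(sol.t_events[2]) > 0:
        return "negative"
    if arrived:
        return "nonnegative"
    raise NumericalError(
        f"orbit neither arrived at the node nor left the nonnegative region "
        f"within z_max={z_max} (c={c}, final rho={sol.y[0][-1]:.3e}, N={sol.y[1][-1]:.3e})"
    )


def wave_speed_phase_space(
    params: ModelParameters,
    tol: float | None = None,
    **classify_kwargs,
) -> WaveSpeedResult:
    """Minimal wave speed with a non-negative density orbit, by bisection.

    The bracket starts at [c_min/2, 2*c_max] (closed-form constant-diffusion
    bounds) and is widened once if the upper end misclassifies.
    """
    lo_bound = c_min(params)
    hi_bound = c_max(params)
    if tol is None:
        tol = 1.0e-3 * hi_bound
    result = WaveSpeedResult(c=float("nan"), bisection_tol=tol, c_min=lo_bound, c_max=hi_bound)

    def label(c):
        lab = classify_trajectory(c, params, **classify_kwargs)
        result.classification_log.append((c, lab))
        return lab

    lo, hi = 0.5 * lo_bound, 2.0 * hi_bound
    if label(lo) == "nonnegative":
        raise NumericalError(
            f"bracket error: lower speed {lo:.4g} already yields a non-negative orbit"
        )
    for _ in range(4):
        if label(hi) == "nonnegative":
            break
        hi *= 2.0
    else:
        raise NumericalError(f"bracket error: no non-negative orbit up to c={hi:.4g}")

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if label(mid) == "nonnegative":
            hi = mid
        else:
            lo = mid
    result.c = hi
    result.converged = True
    return result
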