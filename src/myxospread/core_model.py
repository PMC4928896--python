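"""Parameters and constitutive laws for EPS-gated social-motility expansion.

The model couples three fields on a radial domain: cell density ``rho``, a
growth-limiting nutrient ``N`` and a non-diffusing exopolysaccharide (EPS)
field ``e``.  Cells perform a run-and-reverse random walk whose coarse-grained
diffusion coefficient is gated by the local EPS level,

    D(e) = D0 + Dp * phi(e),        phi(e) = e^m / (e0^m + e^m),

where ``phi`` plays the role of the probability that a type-IV-pilus
retraction succeeds: it vanishes without EPS and saturates at high EPS.
Per-capita growth follows Monod kinetics,

    g(N) = gmax * N / (N0 + N),

and EPS is produced by cells and decays (dries) at constant rates,

    de/dt = alpha * rho - beta * e.

Canonical internal units are micrometres and minutes.  Growth and EPS rates
are usually quoted per hour; use :meth:`ModelParameters.with_hour_rates` or
the config loader (:mod:`myxospread.io`) to convert on construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

MIN_PER_HOUR = 60.0

__all__ = [
    "MIN_PER_HOUR",
    "ModelParameters",
    "hill_phi",
    "diffusion_coefficient",
    "monod_growth",
    "eps_rhs",
    "estimate_Dp_from_motility",
    "growth_rate_from_doubling",
]


@dataclass(frozen=True)
class ModelParameters:
    """All model constants, stored in canonical units (um, min).

    Parameters
    ----------
    D0 : float
        Basal (S-motility independent) cell diffusion coefficient, um^2/min.
    Dp : float
        Maximal additional diffusion coefficient due to S motility, um^2/min.
    DN : float
        Nutrient diffusion coefficient in the agar, um^2/min.
    m : float
        Hill coefficient of the EPS gating function; m >= 1.
    e0 : float
        EPS half-saturation level.  The EPS scale is arbitrary, so e0 = 1 is
        the conventional choice; see the rescaling invariance note below.
    alpha : float
        EPS production rate per unit cell density, EPS-units/(density * min).
        With the conventional e0 = 1 this is the rescaled alpha/e0.
    beta : float
        EPS drying/degradation rate, 1/min.
    gmax : float
        Maximum per-capita growth rate, 1/min.
    N0 : float
        Nutrient half-saturation, a.u./um^2.
    Nin : float
        Initial (uniform) nutrient level, a.u./um^2.  Nutrient units are
        chosen so that nutrient converts 1:1 into cell density.
    c0 : float
        Boundary dispersal flux coefficient, 1/um: the imposed cell-density
        gradient at the inoculum edge is c0 * rho_edge.
    rho_edge : float
        Inoculum cell density at the spot edge (density units); sets the
        strength of the boundary influx and hence the initial-density
        dependence of the expansion.
    r0, rb : float
        Inner (inoculum edge) and outer domain radii, um.
    vg, f : float, optional
        Single-cell gliding speed (um/min) and reversal frequency (1/min);
        only used to estimate Dp via the velocity-jump relation vg^2/(2 f).

    Notes
    -----
    Rescaling invariance: the EPS unit is arbitrary.  Simulating with
    ``(e0=k, alpha=a)`` is equivalent to ``(e0=1, alpha=a/k)`` with the EPS
    field rescaled by ``k``; the cell-density and nutrient fields coincide.
    """

    D0: float = 2.0
    Dp: float = 220.0
    DN: float = 1.0e4
    m: float = 4.0
    e0: float = 1.0
    alpha: float = 19.0 / MIN_PER_HOUR
    beta: float = 16.0 / MIN_PER_HOUR
    gmax: float = 0.173 / MIN_PER_HOUR
    N0: float = 0.1
    Nin: float = 3.0
    c0: float = 0.003
    rho_edge: float = 1.0
    r0: float = 1700.0
    rb: float = 31700.0
    vg: float | None = None
    f: float | None = None

    def __post_init__(self) -> None:
        problems = []
        for name in ("D0", "Dp", "DN", "alpha", "beta", "gmax", "c0", "rho_edge"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0 (got {getattr(self, name)!r})")
        if self.m < 1:
            problems.append(f"m must be >= 1 (got {self.m!r})")
        if self.e0 <= 0:
            problems.append(f"e0 must be > 0 (got {self.e0!r})")
        if self.N0 <= 0:
            problems.append(f"N0 must be > 0 (got {self.N0!r})")
        if self.Nin <= 0:
            problems.append(f"Nin must be > 0 (got {self.Nin!r})")
        if not (self.rb > self.r0 > 0):
            problems.append(f"need rb > r0 > 0 (got r0={self.r0!r}, rb={self.rb!r})")
        for name in ("vg", "f"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                problems.append(f"{name} must be > 0 when given (got {value!r})")
        if problems:
            raise ConfigurationError("invalid ModelParameters: " + "; ".join(problems))

    @classmethod
    def with_hour_rates(
        cls,
        *,
        gmax: float = 0.173,
        alpha: float = 19.0,
        beta: float = 16.0,
        **kwargs,
    ) -> "ModelParameters":
        """Construct with growth/EPS rates given per hour (as in figure captions)."""
        return cls(
            gmax=gmax / MIN_PER_HOUR,
            alpha=alpha / MIN_PER_HOUR,
            beta=beta / MIN_PER_HOUR,
            **kwargs,
        )

    def evolve(self, **changes) -> "ModelParameters":
        """Return a copy with the given canonical-unit fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def gmax_per_hour(self) -> float:
        return self.gmax * MIN_PER_HOUR

    @property
    def alpha_per_hour(self) -> float:
        return self.alpha * MIN_PER_HOUR

    @property
    def beta_per_hour(self) -> float:
        return self.beta * MIN_PER_HOUR

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_float_array(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _maybe_scalar(arr, like):
    if np.ndim(like) == 0:
        return float(arr)
    return arr


def hill_phi(e, e0: float = 1.0, m: float = 4.0):
    """Hill gating function phi(e) = e^m / (e0^m + e^m).

    Interpreted as the probability that a pilus retraction succeeds at local
    EPS level ``e``.  Monotone non-decreasing, phi(0) = 0, phi(e0) = 1/2 and
    phi -> 1 as e -> inf.

    Parameters
    ----------
    e : float or array_like
        EPS level(s), >= 0.
    e0 : float
        Half-saturation level, > 0.
    m : float
        Hill coefficient, >= 1.
    """
    if e0 <= 0:
        raise ValueError("e0 must be > 0")
    if m < 1:
        raise ValueError("Hill coefficient m must be >= 1")
    e_arr = _as_float_array(e, "e")
    t = e_arr / e0
    # Evaluate in a form that stays finite for very large e (t^m overflows).
    with np.errstate(over="ignore", divide="ignore"):
        small = np.where(t <= 1.0, t, 1.0) ** m
        inv = np.where(t > 1.0, t, np.inf) ** (-m)
    out = np.where(t <= 1.0, small / (1.0 + small), 1.0 / (1.0 + inv))
    return _maybe_scalar(out, e)


def diffusion_coefficient(e, params: ModelParameters):
    """Effective cell diffusion coefficient D(e) = D0 + Dp * phi(e), um^2/min."""
    return params.D0 + params.Dp * hill_phi(e, params.e0, params.m)


def monod_growth(N, params: ModelParameters):
    """Per-capita Monod growth rate g(N) = gmax * N / (N0 + N), 1/min."""
    n_arr = _as_float_array(N, "N")
    out = params.gmax * n_arr / (params.N0 + n_arr)
    return _maybe_scalar(out, N)


def eps_rhs(rho, e, params: ModelParameters):
    """EPS production/decay rate de/dt = alpha * rho - beta * e, per minute.

    The fixed point for frozen cell density is e* = alpha * rho / beta.
    """
    rho_arr = _as_float_array(rho, "rho")
    e_arr = _as_float_array(e, "e")
    out = params.alpha * rho_arr - params.beta * e_arr
    if np.ndim(rho) == 0 and np.ndim(e) == 0:
        return float(out)
    return out


def estimate_Dp_from_motility(vg: float, f: float) -> float:
    """Velocity-jump estimate of the S-motility diffusion coefficient.

    A cell gliding at speed ``vg`` and reversing direction as a Poisson
    process with frequency ``f`` diffuses, over times long compared to the
    reversal period, with coefficient Dp ~ vg^2 / (2 f).

    Parameters
    ----------
    vg : float
        Gliding speed, um/min (observed range 4-7).
    f : float
        Reversal frequency, 1/min (observed range 0.1-0.2).
    """
    if vg <= 0 or f <= 0:
        raise ValueError("vg and f must be > 0")
    return vg**2 / (2.0 * f)


def growth_rate_from_doubling(t_double: float) -> float:
    """Exponential growth rate ln(2)/t_double.

    Input and output share a time unit: a doubling time in hours yields a
    rate per hour.
    """
    if t_double <= 0:
        raise ValueError("doubling time must be > 0")
    return math.log(2.0) / t_double
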