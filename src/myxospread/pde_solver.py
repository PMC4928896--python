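"""Crank-Nicolson integration of the coupled expansion equations.

The three fields evolve on an annular radial domain [r0, rb]:

    d rho / dt = (1/r) d/dr ( r D(e) d rho / dr ) + g(N) rho
    d N   / dt = (1/r) d/dr ( r D_N  d N   / dr ) - g(N) rho
    d e   / dt = alpha rho - beta e

with initial condition rho = e = 0, N = Nin, an imposed inward cell-density
gradient c0 * rho_edge at the inoculum edge r0 (cells dispersing from the
initial spot), no-flux for rho at rb and no-flux for N and e at both ends.

Discretisation: vertex-centred finite volumes (exact discrete conservation,
face-centred radii, arithmetic-mean diffusivity at faces) with a
Crank-Nicolson solve for the two diffusion operators.  Each step performs
  (i)   exact exponential update of e over dt with rho frozen,
  (ii)  CN diffusion solves for rho (D evaluated at the updated EPS field)
        and N,
  (iii) explicit Monod growth/consumption using the post-diffusion N,
        with consumption capped at the available nutrient so the 1:1
        nutrient-to-density bookkeeping is exact and N stays >= 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.linalg import solve_banded

from .core_model import ModelParameters, diffusion_coefficient
from .exceptions import ConfigurationError, NumericalError

logger = logging.getLogger(__name__)

#: values in (-CLIP_TOL, 0) produced by the implicit solve are clipped to 0;
#: anything more negative raises NumericalError.  CN undershoots slightly at
#: the sharp front, so the tolerance is scaled by the field's current maximum.
CLIP_TOL_REL = 1e-8

__all__ = ["RadialGrid", "FieldState", "SimulationResult", "initial_state", "step", "simulate"]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centred grid on [r0, rb] with n nodes."""

    r0: float
    rb: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigurationError(f"grid needs n >= 3 nodes (got {self.n})")
        if not (self.rb > self.r0 > 0):
            raise ConfigurationError(f"need rb > r0 > 0 (got r0={self.r0}, rb={self.rb})")

    @classmethod
    def from_spacing(cls, r0: float, rb: float, dx: float) -> "RadialGrid":
        n = int(round((rb - r0) / dx)) + 1
        return cls(r0, rb, n)

    @classmethod
    def for_params(cls, params: ModelParameters, dx: float = 30.0) -> "RadialGrid":
        return cls.from_spacing(params.r0, params.rb, dx)

    @property
    def dx(self) -> float:
        return (self.rb - self.r0) / (self.n - 1)

    @cached_property
    def nodes(self) -> np.ndarray:
        return self.r0 + self.dx * np.arange(self.n)

    @cached_property
    def faces(self) -> np.ndarray:
        """Interior face radii (length n-1)."""
        return self.nodes[:-1] + 0.5 * self.dx

    @cached_property
    def volumes(self) -> np.ndarray:
        """Finite-volume cell measures int r dr per node (length n)."""
        edges = np.concatenate(([self.r0], self.faces, [self.rb]))
        return 0.5 * (edges[1:] ** 2 - edges[:-1] ** 2)


@dataclass
class FieldState:
    """The three fields at one time point (t in minutes)."""

    t: float
    rho: np.ndarray
    N: np.ndarray
    e: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.rho.copy(), self.N.copy(), self.e.copy())

    def validate(self) -> None:
        for name in ("rho", "N", "e"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"non-finite values in field '{name}' at t={self.t} min")
            if np.any(arr < 0):
                raise NumericalError(f"negative values in field '{name}' at t={self.t} min")


@dataclass
class SimulationResult:
    """Snapshots at requested output times plus the run definition."""

    params: ModelParameters
    grid: RadialGrid
    dt: float
    snapshots: list[FieldState] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def total_cell_mass(self, state: FieldState) -> float:
        """Discrete cell mass  sum_i rho_i * w_i  (per unit angle)."""
        return float(np.dot(self.grid.volumes, state.rho))


def initial_state(params: ModelParameters, grid: RadialGrid) -> FieldState:
    """Empty annulus: rho = e = 0 and N = Nin everywhere at t = 0."""
    if not (np.isclose(grid.r0, params.r0) and np.isclose(grid.rb, params.rb)):
        raise ConfigurationError(
            f"grid [{grid.r0}, {grid.rb}] does not match params [{params.r0}, {params.rb}]"
        )
    n = grid.n
    return FieldState(0.0, np.zeros(n), np.full(n, float(params.Nin)), np.zeros(n))


def _cn_solve(u, d_face, grid, dt, source0=0.0):
    """One Crank-Nicolson step of du/dt = (1/r) d/dr(r D du/dr) + b.

    ``d_face`` holds the diffusivity at the n-1 interior faces; boundary
    faces carry no diffusive flux.  ``source0`` is the rate injected into
    node 0 by the inoculum-edge influx (already divided by the cell volume).
    """
    k = grid.faces * d_face / grid.dx  # face conductances
    w = grid.volumes
    sup = np.zeros_like(u)
    sub = np.zeros_like(u)
    diag = np.zeros_like(u)
    sup[:-1] = k / w[:-1]            # coupling to node i+1, rows 0..n-2
    sub[1:] = k / w[1:]              # coupling to node i-1, rows 1..n-1
    diag[:-1] -= k / w[:-1]
    diag[1:] -= k / w[1:]

    # rhs = (I + dt/2 A) u + dt * src
    au = diag * u
    au[:-1] += sup[:-1] * u[1:]
    au[1:] += sub[1:] * u[:-1]
    rhs = u + 0.5 * dt * au
    rhs[0] += dt * source0

    ab = np.zeros((3, u.size))
    ab[0, 1:] = -0.5 * dt * sup[:-1]
    ab[1, :] = 1.0 - 0.5 * dt * diag
    ab[2, :-1] = -0.5 * dt * sub[1:]
    return solve_banded((1, 1), ab, rhs)


def _clip_field(arr, name, t, clip_tol):
    low = arr.min()
    if low < -clip_tol:
        raise NumericalError(
            f"field '{name}' fell to {low:.3e} (< -{clip_tol:.1e}) at t={t:.2f} min"
        )
    np.clip(arr, 0.0, None, out=arr)
    return arr


def step(
    state: FieldState,
    params: ModelParameters,
    grid: RadialGrid,
    dt: float,
) -> FieldState:
    """Advance all three fields by one time step of length dt minutes."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rho, N, e, t = state.rho, state.N, state.e, state.t

    # (i) EPS: linear ODE in e, integrated exactly with rho frozen.
    if params.beta > 0:
        decay = np.exp(-params.beta * dt)
        e_new = e * decay + (params.alpha * rho / params.beta) * (1.0 - decay)
    else:
        e_new = e + params.alpha * rho * dt

    # (ii) diffusion (CN).  D is evaluated at the updated EPS field and
    # lagged within the step (semi-implicit linearisation).
    d_nodes = diffusion_coefficient(e_new, params)
    d_face = 0.5 * (d_nodes[:-1] + d_nodes[1:])
    # Influx through the inoculum edge: the spot (r < r0) holds density
    # rho_edge and accumulates its own EPS, e_spot(t) = (alpha rho_edge /
    # beta)(1 - exp(-beta t)), so cells disperse out of it at the gated flux
    # D(e_spot) * c0 * rho_edge.  Dense spots activate S motility within
    # minutes; sparse spots stay near the basal flux D0 * c0 * rho_edge.
    if params.beta > 0:
        e_spot = (params.alpha * params.rho_edge / params.beta) * (
            1.0 - np.exp(-params.beta * t)
        )
    else:
        e_spot = params.alpha * params.rho_edge * t
    influx = diffusion_coefficient(e_spot, params) * params.c0 * params.rho_edge
    source0 = grid.r0 * influx / grid.volumes[0]
    rho_new = _cn_solve(rho, d_face, grid, dt, source0=source0)
    if params.DN > 0:
        dn_face = np.full(grid.n - 1, float(params.DN))
        n_new = _cn_solve(N, dn_face, grid, dt)
    else:
        n_new = N.copy()

    # (iii) growth with 1:1 nutrient consumption, capped at available N.
    monod = n_new / (params.N0 + np.maximum(n_new, 0.0))
    q = params.gmax * dt * rho_new * monod
    np.minimum(q, np.maximum(n_new, 0.0), out=q)
    np.maximum(q, 0.0, out=q)
    rho_new = rho_new + q
    n_new = n_new - q

    for name, arr in (("rho", rho_new), ("N", n_new), ("e", e_new)):
        if not np.all(np.isfinite(arr)):
            raise NumericalError(f"non-finite values in field '{name}' at t={t + dt:.2f} min")
    scale_rho = max(rho_new.max(), params.Nin)
    _clip_field(rho_new, "rho", t + dt, CLIP_TOL_REL * scale_rho)
    _clip_field(n_new, "N", t + dt, CLIP_TOL_REL * params.Nin)
    # diffusion cannot push N above its max principle bound except by rounding
    np.clip(n_new, None, params.Nin, out=n_new)

    return FieldState(t + dt, rho_new, n_new, e_new)


def simulate(
    params: ModelParameters,
    grid: RadialGrid | None = None,
    t_end: float = 0.0,
    output_times=None,
    dt: float = 0.05,
    initial: FieldState | None = None,
) -> SimulationResult:
    """Integrate the model to ``t_end`` minutes, snapshotting at ``output_times``.

    Snapshots are taken at the step nearest each requested time (no
    interpolation).  The first snapshot is always the initial condition.
    Identical inputs give bit-identical outputs.
    """
    if grid is None:
        grid = RadialGrid.for_params(params)
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    state = initial.copy() if initial is not None else initial_state(params, grid)

    d_worst = max(params.DN, params.D0 + params.Dp)
    if d_worst * dt / grid.dx**2 > 50:
        warnings.warn(
            f"diffusion number {d_worst * dt / grid.dx ** 2:.1f} > 50; "
            "Crank-Nicolson stays stable but accuracy degrades",
            stacklevel=2,
        )

    n_steps = int(round(t_end / dt))
    if output_times is None:
        output_times = [t_end]
    requested = sorted(set(float(t) for t in output_times))
    if requested and (requested[0] < 0 or requested[-1] > t_end + 0.5 * dt):
        raise ValueError("output_times must lie within [0, t_end]")
    out_steps = sorted({min(int(round(t / dt)), n_steps) for t in requested} | {0})

    result = SimulationResult(params=params, grid=grid, dt=dt)
    out_iter = iter(out_steps)
    next_out = next(out_iter)
    for k in range(n_steps + 1):
        if k == next_out:
            result.snapshots.append(state.copy())
            next_out = next(out_iter, None)
            if next_out is None:
                break
        if k < n_steps:
            state = step(state, params, grid, dt)
    return result
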