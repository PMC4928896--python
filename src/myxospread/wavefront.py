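"""Front position, expansion rate, steady speed and lag-phase extraction.

The colony front is the outermost radius where the cell density crosses a
low threshold (rho* ~ 0.01 in simulation density units).  A trajectory of
front positions yields the instantaneous expansion rate (finite
differences), the steady-state speed (linear fit over the late-time window)
and the lag duration: the transient slow-expansion phase before the rate
first reaches a given fraction of the steady speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError
from .pde_solver import FieldState, RadialGrid, SimulationResult

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01

__all__ = [
    "DEFAULT_THRESHOLD",
    "FrontTrajectory",
    "LagSummary",
    "front_position",
    "front_trajectory",
    "expansion_rate_series",
    "steady_state_speed",
    "lag_duration",
    "analyze_front",
]


@dataclass
class FrontTrajectory:
    """Time series of front position (times in minutes, radii in um)."""

    times: np.ndarray
    front_radius: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.front_radius = np.asarray(self.front_radius, dtype=float)
        if self.times.size != self.front_radius.size:
            raise InputError("times and front_radius must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")

    @property
    def midpoint_times(self) -> np.ndarray:
        return 0.5 * (self.times[:-1] + self.times[1:])


@dataclass
class LagSummary:
    lag_duration: float          # min
    steady_speed: float          # um/min
    steady_window: tuple         # (t_start, t_end) of the speed fit, min
    r_squared: float
    no_takeoff: bool = False


def front_position(state: FieldState, grid: RadialGrid, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Outermost radius where rho crosses ``threshold`` (linear interpolation).

    Returns grid.r0 if the density is below threshold everywhere, and
    grid.rb (with a logged note) if it is above threshold at the outer edge.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rho = state.rho
    above = np.nonzero(rho >= threshold)[0]
    if above.size == 0:
        logger.debug("front_position: density below threshold everywhere at t=%s", state.t)
        return float(grid.r0)
    j = int(above[-1])
    if j == grid.n - 1:
        logger.info("front_position: front reached the outer boundary at t=%s", state.t)
        return float(grid.rb)
    r = grid.nodes
    frac = (rho[j] - threshold) / (rho[j] - rho[j + 1])
    return float(r[j] + frac * (r[j + 1] - r[j]))


def front_width(state: FieldState, grid: RadialGrid, low_level: float, high_level: float) -> float:
    """Width of the leading edge: distance between the outermost radii where
    rho crosses ``low_level`` and ``high_level`` (interpolated).

    For a traveling front connecting rho ~ Nin (behind) to 0 (ahead),
    levels of 0.1*Nin and 0.9*Nin measure the rise width of the profile; a
    fixed front shape gives a constant width between late snapshots.
    """
    if not 0 < low_level < high_level:
        raise ValueError("need 0 < low_level < high_level")
    return front_position(state, grid, low_level) - front_position(state, grid, high_level)


def front_trajectory(result: SimulationResult, threshold: float = DEFAULT_THRESHOLD) -> FrontTrajectory:
    """Front position at every snapshot of a simulation."""
    times = result.times
    radii = np.array([front_position(s, result.grid, threshold) for s in result.snapshots])
    return FrontTrajectory(times, radii, threshold)


def expansion_rate_series(traj: FrontTrajectory) -> np.ndarray:
    """Finite-difference expansion rate, um/min, at interval midpoints."""
    if traj.times.size < 2:
        raise InputError("need at least 2 time points for an expansion rate")
    return np.diff(traj.front_radius) / np.diff(traj.times)


def steady_state_speed(traj: FrontTrajectory, window_fraction: float = 0.2):
    """Least-squares slope of front position over the trailing time window.

    Returns ``(speed, (t_start, t_end), r_squared)``.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    t, r = traj.times, traj.front_radius
    if t.size < 2:
        raise InputError("trajectory too short for a speed fit")
    t_start = t[-1] - window_fraction * (t[-1] - t[0])
    mask = t >= t_start
    if mask.sum() < 5:
        raise InputError(
            f"late-time window holds {int(mask.sum())} points; need >= 5 for a speed fit"
        )
    fit = stats.linregress(t[mask], r[mask])
    return float(fit.slope), (float(t[mask][0]), float(t[-1])), float(fit.rvalue**2)


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average with shrunk edge windows."""
    if x.size < 3:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def lag_duration(
    traj: FrontTrajectory,
    steady_speed: float,
    fraction: float = 0.5,
) -> tuple[float, bool]:
    """Duration of the slow-expansion transient, minutes.

    The lag ends at the earliest interval midpoint where the (3-point
    smoothed) expansion rate first exceeds ``fraction * steady_speed``; 0 if
    already exceeded on the first interval.  Returns ``(lag, no_takeoff)``
    where ``no_takeoff`` flags a trajectory that never reaches the target
    rate (the total duration is then returned as the lag).
    """
    if steady_speed <= 0:
        raise InputError("steady_speed must be > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rate = _smooth3(expansion_rate_series(traj))
    above = np.nonzero(rate > fraction * steady_speed)[0]
    if above.size == 0:
        logger.warning("lag_duration: expansion rate never reached %.3g of steady speed", fraction)
        return float(traj.times[-1] - traj.times[0]), True
    i = int(above[0])
    if i == 0:
        return 0.0, False
    return float(traj.midpoint_times[i] - traj.times[0]), False


def analyze_front(
    traj: FrontTrajectory,
    window_fraction: float = 0.2,
    lag_fraction: float = 0.5,
) -> LagSummary:
    """Steady speed and lag duration in one record."""
    speed, window, r2 = steady_state_speed(traj, window_fraction)
    lag, no_takeoff = lag_duration(traj, speed, lag_fraction)
    return LagSummary(lag, speed, window, r2, no_takeoff)
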