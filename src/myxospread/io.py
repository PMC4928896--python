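"""Configuration files, profile CSVs and run manifests.

Configs are YAML with three blocks::

    units:
      rate: per_hour        # applies to gmax, alpha, beta
      length: um
    parameters:
      D0: 2.0
      ...
    solver:                 # optional
      dx: 30.0
      dt: 0.05

All tabular output is plain CSV; manifests are YAML.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import MIN_PER_HOUR, ModelParameters
from .exceptions import ConfigurationError, InputError
from .pde_solver import FieldState, RadialGrid

__all__ = [
    "load_config",
    "save_config",
    "bundled_config_path",
    "write_profile_csv",
    "read_profile_csv",
    "RunManifest",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_RATE_FIELDS = ("gmax", "alpha", "beta")
_SOLVER_KEYS = {"dx", "dt"}


def bundled_config_path(name: str) -> Path:
    """Path to a packaged config, e.g. ``soft_agar`` or ``soft_agar.yaml``."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    path = resources.files("myxospread.configs") / name
    if not path.is_file():
        available = sorted(p.name for p in resources.files("myxospread.configs").iterdir())
        raise ConfigurationError(f"no bundled config {name!r}; available: {available}")
    return Path(str(path))


def load_config(path) -> tuple[ModelParameters, dict]:
    """Load and validate a config file; returns (params, solver settings).

    Parameters are unit-canonicalised to um/min.  Unknown keys are rejected;
    every problem found is reported in one error message.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a key-value mapping")

    problems = []
    unknown_blocks = set(raw) - {"units", "parameters", "solver"}
    if unknown_blocks:
        problems.append(f"unknown top-level keys: {sorted(unknown_blocks)}")
    units = raw.get("units", {}) or {}
    rate_unit = units.get("rate", "per_min")
    if rate_unit not in ("per_min", "per_hour"):
        problems.append(f"units.rate must be per_min or per_hour, got {rate_unit!r}")
    if units.get("length", "um") != "um":
        problems.append(f"units.length must be um, got {units.get('length')!r}")

    values = dict(raw.get("parameters", {}) or {})
    unknown = set(values) - _PARAM_FIELDS
    if unknown:
        problems.append(f"unknown parameters: {sorted(unknown)}")
        for key in unknown:
            values.pop(key)
    if rate_unit == "per_hour":
        for key in _RATE_FIELDS:
            if key in values:
                values[key] = values[key] / MIN_PER_HOUR

    solver = dict(raw.get("solver", {}) or {})
    unknown_solver = set(solver) - _SOLVER_KEYS
    if unknown_solver:
        problems.append(f"unknown solver keys: {sorted(unknown_solver)}")
    if problems:
        raise ConfigurationError(f"invalid config {path}: " + "; ".join(problems))
    try:
        params = ModelParameters(**values)
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
    return params, solver


def save_config(params: ModelParameters, path, solver: dict | None = None) -> None:
    """Write a config that round-trips through :func:`load_config`."""
    values = params.to_dict()
    values = {k: v for k, v in values.items() if v is not None}
    doc = {
        "units": {"rate": "per_min", "length": "um"},
        "parameters": values,
    }
    if solver:
        doc["solver"] = dict(solver)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_profile_csv(state: FieldState, grid: RadialGrid, path) -> None:
    """Radial profile as CSV (columns r_um, rho, N, e); t stored in a comment."""
    with open(path, "w") as fh:
        fh.write(f"# t_min={state.t!r}\n")
        pd.DataFrame(
            {"r_um": grid.nodes, "rho": state.rho, "N": state.N, "e": state.e}
        ).to_csv(fh, index=False)


def read_profile_csv(path) -> tuple[FieldState, RadialGrid]:
    """Inverse of :func:`write_profile_csv`; validates the fields."""
    t = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# t_min="):
            t = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    missing = {"r_um", "rho", "N", "e"} - set(df.columns)
    if missing:
        raise InputError(f"profile {path} missing columns: {sorted(missing)}")
    if len(df) < 3:
        raise InputError(f"profile {path} holds {len(df)} rows; need >= 3")
    r = df["r_um"].to_numpy(dtype=float)
    grid = RadialGrid(float(r[0]), float(r[-1]), len(r))
    if not np.allclose(r, grid.nodes, rtol=0, atol=1e-6):
        raise InputError(f"profile {path} radii are not a uniform grid")
    state = FieldState(
        t,
        df["rho"].to_numpy(dtype=float),
        df["N"].to_numpy(dtype=float),
        df["e"].to_numpy(dtype=float),
    )
    state.validate()
    return state, grid


def _tool_version() -> str:
    try:
        return metadata.version("myxospread")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    command: str
    params: dict
    solver: dict = field(default_factory=dict)
    seed: int | None = None
    config_path: str | None = None
    version: str = field(default_factory=_tool_version)
    timestamp: str = field(default_factory=lambda: datetime.datetime.now().isoformat())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
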