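"""Configuration parsing, bundled parameter fixtures and trajectory CSV I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .integrate import Trajectory
from .model import InvalidInputError, ModelParameters

__all__ = [
    "FixtureSet",
    "FIXTURE_NAMES",
    "get_fixture",
    "fixture_path",
    "load_config",
    "write_trajectory",
    "read_trajectory",
]

PARAM_KEYS = ("B", "alpha", "m", "beta", "epsilon", "gamma1", "gamma2", "mu", "lam")
# optional keys describing a control problem / simulation on top of the model
OPTIONAL_KEYS = (
    "m_as_control", "initial", "tf", "dt", "c1", "c2",
    "relaxation", "tol", "max_iter",
)

FIXTURE_NAMES = ("set_A", "set_B", "set_C", "set_D")

_PROVENANCE = {
    "set_A": "extinction scenario, R0 = 0.681 < 1",
    "set_B": "persistence scenario, R0 = 1.275 > 1",
    "set_C": "control scenario (m, beta promoted to controls; "
             "stored values are constant-strategy baselines)",
    "set_D": "high-immigration control scenario (baseline beta = 0.06 variant)",
}


@dataclass(frozen=True)
class FixtureSet:
    name: str
    params: ModelParameters
    provenance: str


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture config (usable as ``--config``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(str(resources.files("s2eir").joinpath(f"fixtures/{name}.json")))


def get_fixture(name: str) -> FixtureSet:
    """Load one of the bundled parameter sets by name."""
    cfg = load_config(fixture_path(name))
    return FixtureSet(name=name, params=cfg["params"], provenance=_PROVENANCE[name])


def load_config(path) -> dict:
    """Read and validate a JSON/YAML model configuration.

    The nine parameter keys ``B, alpha, m, beta, epsilon, gamma1, gamma2,
    mu, lam`` are all required; the control/simulation keys in
    ``OPTIONAL_KEYS`` may be present; anything else is rejected by name.
    Every violation is collected and reported in a single error.

    Returns a dict with ``params`` (a validated :class:`ModelParameters`)
    plus whichever optional keys were present.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config {path} did not parse to a mapping")

    problems = []
    unknown = sorted(set(raw) - set(PARAM_KEYS) - set(OPTIONAL_KEYS))
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    missing = [k for k in PARAM_KEYS if k not in raw]
    if missing:
        problems.append(f"missing required keys: {', '.join(missing)}")
    if problems:
        raise InvalidInputError(f"invalid config {path}: " + "; ".join(problems))

    try:
        params = ModelParameters(
            **{k: raw[k] for k in PARAM_KEYS},
            m_as_control=bool(raw.get("m_as_control", False)),
        )
    except InvalidInputError as err:
        raise InvalidInputError(
            f"invalid config {path}: parameter bounds violated "
            f"(all rates must be > 0, m within its interval): {err}"
        ) from err

    out: dict = {"params": params}
    for key in OPTIONAL_KEYS:
        if key in raw:
            out[key] = raw[key]
    return out


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["t", "S", "E1", "E2", "I", "R", "m", "beta"]


def write_trajectory(
    traj: Trajectory, path, params: ModelParameters | None = None
) -> None:
    """Write a trajectory as CSV with header ``t,S,E1,E2,I,R,m,beta``.

    Full double precision (round-trips bit-exactly through
    :func:`read_trajectory`).  A trajectory without a control schedule
    gets the constant ``params.m`` / ``params.beta`` columns.
    """
    if traj.controls is not None:
        controls = traj.controls
    elif params is not None:
        controls = np.tile([params.m, params.beta], (len(traj.times), 1))
    else:
        raise InvalidInputError(
            "trajectory has no controls; pass params to fill the m/beta columns"
        )
    df = pd.DataFrame(
        np.column_stack([traj.times, traj.states, controls]),
        columns=_CSV_COLUMNS,
    )
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as err:
        raise OSError(f"failed writing trajectory to {path}: {err}") from err


def read_trajectory(path) -> Trajectory:
    """Inverse of :func:`write_trajectory`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _CSV_COLUMNS:
        raise InvalidInputError(
            f"{path}: expected columns {_CSV_COLUMNS}, got {list(df.columns)}"
        )
    return Trajectory(
        times=df["t"].to_numpy(),
        states=df[["S", "E1", "E2", "I", "R"]].to_numpy(),
        controls=df[["m", "beta"]].to_numpy(),
    )
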