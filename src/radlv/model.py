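"""Core types and vector field for the switched Lotka-Volterra radiotherapy model.

Two cell populations compete in a tissue region: healthy cells ``x1`` and
cancer cells ``x2``.  Without treatment the dynamics are classical
Lotka-Volterra competition.  Radiotherapy is modelled as a periodic
piecewise-constant harvesting term: during the first ``L`` hours of every
``omega``-hour period the dose rate is ``gamma``; cancer cells are harvested
at rate ``gamma * x2`` and healthy cells, as collateral damage, at rate
``epsilon * gamma * x1``::

    dx1/dt = alpha1*x1*(1 - x1/K1) - beta1*x1*x2 - epsilon*D(t)*x1
    dx2/dt = alpha2*x2*(1 - x2/K2) - beta2*x1*x2 -         D(t)*x2

with D(t) = gamma on [n*omega, n*omega + L) and 0 otherwise.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "TreatmentSchedule",
    "State",
    "Trajectory",
    "dose",
    "vector_field",
    "load_config",
    "dump_config",
]

#: treat (t mod omega) within this of omega as wrapped to 0, so that switch-node
#: evaluations are deterministic under floating-point round-off
_MOD_GUARD = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """The seven biological constants of the competition model.

    Parameters
    ----------
    alpha1, alpha2 : float
        Proliferation rates of healthy and cancer cells (per hour).
    K1, K2 : float
        Carrying capacities (dimensionless concentration units).
    beta1, beta2 : float
        Competition coefficients (per concentration per hour).
    epsilon : float
        Fraction of the dose rate felt by healthy cells (collateral-damage
        coefficient, dimensionless, > 0).
    """

    alpha1: float
    alpha2: float
    K1: float
    K2: float
    beta1: float
    beta2: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "K1", "K2", "beta1", "beta2", "epsilon"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Periodic radiotherapy schedule.

    Dose rate ``gamma`` (per hour) is applied during the first ``L`` hours
    of every period of length ``omega`` hours (0 < L < omega).
    """

    gamma: float
    omega: float
    L: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not self.omega > 0:
            raise ValueError("omega must be strictly positive")
        if not 0 < self.L < self.omega:
            raise ValueError("L must satisfy 0 < L < omega")

    def switch_times(self, t_end: float, t_start: float = 0.0) -> np.ndarray:
        """All switch instants n*omega and n*omega + L in [t_start, t_end]."""
        n_max = int(np.floor(t_end / self.omega)) + 1
        pts = []
        for n in range(n_max + 1):
            for t in (n * self.omega, n * self.omega + self.L):
                if t_start < t < t_end:
                    pts.append(t)
        return np.array(sorted(pts))


@dataclass(frozen=True)
class State:
    """Nonnegative concentrations of healthy (x1) and cancer (x2) cells."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("cell concentrations must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)


@dataclass
class Trajectory:
    """Time-stamped states of (x1, x2) with switch times as grid nodes."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    params: ModelParams
    schedule: TreatmentSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 2):
            raise ValueError("states must have shape (len(times), 2)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    def final_state(self) -> State:
        return State(float(self.states[-1, 0]), float(self.states[-1, 1]))

    def dose_values(self) -> np.ndarray:
        return np.array([dose(t, self.schedule) for t in self.times])

    def to_csv(self, path: str | Path) -> None:
        """Write columns time, x1, x2, dose (12 significant digits)."""
        arr = np.column_stack([self.times, self.states, self.dose_values()])
        np.savetxt(
            path,
            arr,
            delimiter=",",
            header="time,x1,x2,dose",
            comments="",
            fmt="%.12g",
        )


def dose(t: float, schedule: TreatmentSchedule) -> float:
    """Piecewise-constant periodic dose rate D(t).

    Returns ``gamma`` when (t mod omega) < L and 0 otherwise; the on-phase is
    the half-open interval [n*omega, n*omega + L), so the dose at t = n*omega
    is gamma and at t = n*omega + L it is 0.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    tm = float(np.mod(t, schedule.omega))
    if tm >= schedule.omega - _MOD_GUARD:
        tm = 0.0
    return schedule.gamma if tm < schedule.L else 0.0


def vector_field(
    t: float,
    s: Sequence[float] | State,
    p: ModelParams,
    schedule: TreatmentSchedule,
) -> np.ndarray:
    """Right-hand side of the switched competition system at time t."""
    if isinstance(s, State):
        x1, x2 = s.x1, s.x2
    else:
        x1, x2 = float(s[0]), float(s[1])
    D = dose(t, schedule)
    dx1 = p.alpha1 * x1 * (1.0 - x1 / p.K1) - p.beta1 * x1 * x2 - p.epsilon * D * x1
    dx2 = p.alpha2 * x2 * (1.0 - x2 / p.K2) - p.beta2 * x1 * x2 - D * x2
    return np.array([dx1, dx2])


# -- config IO ---------------------------------------------------------------

_PARAM_KEYS = ("alpha1", "alpha2", "K1", "K2", "beta1", "beta2", "epsilon")


def load_config(path: str | Path) -> tuple[ModelParams, TreatmentSchedule]:
    """Read ModelParams and TreatmentSchedule from a TOML or YAML file.

    Keys: alpha1..epsilon for the model and gamma, omega, L_on for the
    schedule, either flat or under [model]/[schedule] tables.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    flat: dict = {}
    for key, val in raw.items():
        if isinstance(val, dict):
            flat.update(val)
        else:
            flat[key] = val
    params = ModelParams(**{k: float(flat[k]) for k in _PARAM_KEYS})
    schedule = TreatmentSchedule(
        gamma=float(flat["gamma"]), omega=float(flat["omega"]), L=float(flat["L_on"])
    )
    return params, schedule


def dump_config(
    params: ModelParams, schedule: TreatmentSchedule, path: str | Path
) -> None:
    """Write a flat key-value config (TOML or YAML chosen by extension)."""
    path = Path(path)
    items = {k: getattr(params, k) for k in _PARAM_KEYS}
    items.update(gamma=schedule.gamma, omega=schedule.omega, L_on=schedule.L)
    if path.suffix.lower() == ".toml":
        lines = [f"{k} = {v!r}" for k, v in items.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(yaml.safe_dump(items, sort_keys=False))
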