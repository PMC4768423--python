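"""Seven classical ODE models of solid-tumor growth.

Each model describes the change of tumor volume ``V`` (mm^3) over time
(days) through a single autonomous ODE:

========== =============================
exponential  dV/dt = a V
mendelsohn   dV/dt = a V^b
logistic     dV/dt = a V (1 - V/b)
linear       dV/dt = a V / (V + b)
surface      dV/dt = a V / (V + b)^(1/3)
gompertz     dV/dt = a V ln(b / (V + c))
bertalanffy  dV/dt = a V^(2/3) - b V
========== =============================

Constant-concentration chemotherapy with kill rate ``c0`` (per day) is
modelled by subtracting ``c0 * V`` from each right-hand side.

Units are fixed throughout the package: time in days, volume in mm^3;
rate-like parameters are per day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MODEL_NAMES",
    "PARAM_NAMES",
    "ParameterSet",
    "GrowthModelSpec",
    "ChemoSetting",
    "Trajectory",
    "ModelSpecificationError",
    "DomainError",
    "ClosedFormUnavailable",
    "DegenerateModelWarning",
    "rhs_eval",
    "closed_form_volume",
    "solve_trajectory",
    "with_chemotherapy",
]

MODEL_NAMES: tuple[str, ...] = (
    "exponential",
    "mendelsohn",
    "logistic",
    "linear",
    "surface",
    "gompertz",
    "bertalanffy",
)

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("a",),
    "mendelsohn": ("a", "b"),
    "logistic": ("a", "b"),
    "linear": ("a", "b"),
    "surface": ("a", "b"),
    "gompertz": ("a", "b", "c"),
    "bertalanffy": ("a", "b"),
}

#: Volume above which unbounded growth is declared divergent (mm^3).
DIVERGENCE_THRESHOLD = 1e12


class ModelSpecificationError(ValueError):
    """Unknown model name or wrong parameter count/sign."""


class DomainError(ValueError):
    """Evaluation requested outside the model's domain (e.g. V < 0)."""


class ClosedFormUnavailable(NotImplementedError):
    """No analytic solution is implemented for this model; use the solver."""


class DegenerateModelWarning(UserWarning):
    """A parameter combination degenerates one model into another."""


@dataclass(frozen=True)
class ParameterSet:
    """Positive parameters (a, b, c) of a growth model.

    ``a`` is rate-like (per day); ``b`` is model dependent (a carrying
    capacity-like volume for logistic/linear/surface/gompertz, a
    dimensionless exponent for mendelsohn, a loss rate for bertalanffy);
    ``c`` is the gompertz volume offset (mm^3).
    """

    a: float
    b: float | None = None
    c: float | None = None

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(p for p in (self.a, self.b, self.c) if p is not None)


@dataclass(frozen=True)
class ChemoSetting:
    """Constant drug supply acting on the tumor with kill rate ``c0``/day.

    ``c0 = 0`` reproduces the untreated model exactly.
    """

    c0: float = 0.0

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise DomainError(f"chemotherapy kill rate must be >= 0, got {self.c0}")


NO_CHEMO = ChemoSetting(0.0)


@dataclass(frozen=True)
class GrowthModelSpec:
    """One of the seven named growth models plus its parameter vector."""

    name: str
    params: ParameterSet

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ModelSpecificationError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )
        expected = PARAM_NAMES[self.name]
        supplied = self.params.as_tuple()
        have = tuple(
            n for n, p in zip(("a", "b", "c"), (self.params.a, self.params.b, self.params.c))
            if p is not None
        )
        if have != expected:
            raise ModelSpecificationError(
                f"{self.name} takes parameters {expected}, got {have}"
            )
        if any(p <= 0 for p in supplied):
            raise ModelSpecificationError(
                f"{self.name} parameters must be strictly positive, got {supplied}"
            )
        if self.name == "mendelsohn" and self.params.b == 1.0:
            warnings.warn(
                "mendelsohn with b=1 degenerates to the exponential model; "
                "its doubling-time/cure formulas are singular at b=1",
                DegenerateModelWarning,
                stacklevel=2,
            )

    @classmethod
    def create(
        cls, name: str, a: float, b: float | None = None, c: float | None = None
    ) -> "GrowthModelSpec":
        return cls(name=name, params=ParameterSet(a=a, b=b, c=c))

    @property
    def a(self) -> float:
        return self.params.a

    @property
    def b(self) -> float:
        if self.params.b is None:
            raise AttributeError(f"{self.name} has no parameter b")
        return self.params.b

    @property
    def c(self) -> float:
        if self.params.c is None:
            raise AttributeError(f"{self.name} has no parameter c")
        return self.params.c

    @property
    def k(self) -> int:
        """Number of free ODE parameters (1 for exponential, 3 for gompertz)."""
        return len(PARAM_NAMES[self.name])


@dataclass
class Trajectory:
    """A solved volume trajectory V(t) at the requested times.

    ``diverged`` is set when the volume crossed the divergence threshold
    (or the solver failed) before the last requested time; ``volumes``
    then only covers the times up to ``last_valid_time``.
    """

    times: np.ndarray
    volumes: np.ndarray
    diverged: bool = False
    last_valid_time: float | None = None

    def __len__(self) -> int:
        return len(self.times)


def _raw_rhs(name: str, p: ParameterSet, v: float) -> float:
    # v is assumed clipped to >= 0 by callers; fractional powers of a
    # negative volume would otherwise go complex.
    if name == "exponential":
        return p.a * v
    if name == "mendelsohn":
        return p.a * v ** p.b
    if name == "logistic":
        return p.a * v * (1.0 - v / p.b)
    if name == "linear":
        return p.a * v / (v + p.b)
    if name == "surface":
        return p.a * v / (v + p.b) ** (1.0 / 3.0)
    if name == "gompertz":
        if v == 0.0:
            return 0.0
        return p.a * v * math.log(p.b / (v + p.c))
    if name == "bertalanffy":
        return p.a * v ** (2.0 / 3.0) - p.b * v
    raise ModelSpecificationError(name)


def rhs_eval(
    model: GrowthModelSpec, v: float, chemo: ChemoSetting | None = None
) -> float:
    """Growth rate dV/dt (mm^3/day) at volume ``v``, minus any ``c0*v`` kill term.

    Raises :class:`DomainError` for ``v < 0``.
    """
    if v < 0:
        raise DomainError(f"volume must be >= 0, got {v}")
    c0 = chemo.c0 if chemo is not None else 0.0
    return _raw_rhs(model.name, model.params, float(v)) - c0 * float(v)


def with_chemotherapy(
    model: GrowthModelSpec, c0: float
) -> Callable[[float, float], float]:
    """Return the treated right-hand side ``f(t, v)`` = untreated RHS − c0·v."""
    if c0 < 0:
        raise DomainError(f"chemotherapy kill rate must be >= 0, got {c0}")
    chemo = ChemoSetting(c0)

    def rhs(t: float, v: float) -> float:  # autonomous; t ignored
        return rhs_eval(model, max(float(v), 0.0), chemo)

    return rhs


def closed_form_volume(model: GrowthModelSpec, v0: float, t):
    """Analytic V(t) for the untreated models that admit one.

    Implemented for exponential, logistic, mendelsohn (b != 1) and
    bertalanffy.  The gompertz form with a positive offset c, and the
    linear/surface forms, have no elementary solution; those raise
    :class:`ClosedFormUnavailable` and callers fall back to
    :func:`solve_trajectory`.  ``t`` may be a scalar or array of days
    since the time at which ``V = v0``.  Finite-time blow-up
    (mendelsohn b > 1) returns ``inf`` past the blow-up time.
    """
    if v0 <= 0:
        raise DomainError(f"initial volume must be > 0, got {v0}")
    t = np.asarray(t, dtype=float)
    p = model.params
    name = model.name
    if name == "exponential":
        with np.errstate(over="ignore"):
            out = v0 * np.exp(p.a * t)
    elif name == "logistic":
        out = p.b / (1.0 + (p.b / v0 - 1.0) * np.exp(-p.a * t))
    elif name == "mendelsohn":
        if p.b == 1.0:
            out = v0 * np.exp(p.a * t)
        else:
            e = 1.0 - p.b
            base = v0 ** e + p.a * e * t
            with np.errstate(invalid="ignore"):
                out = np.where(base > 0, np.abs(base) ** (1.0 / e), np.inf)
    elif name == "bertalanffy":
        u_inf = p.a / p.b
        u = u_inf + (v0 ** (1.0 / 3.0) - u_inf) * np.exp(-p.b * t / 3.0)
        out = u ** 3
    else:
        raise ClosedFormUnavailable(
            f"no elementary solution implemented for the {name} model"
        )
    return float(out) if out.ndim == 0 else out


def solve_trajectory(
    model: GrowthModelSpec,
    v0: float,
    times: Sequence[float],
    chemo: ChemoSetting | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_volume: float = DIVERGENCE_THRESHOLD,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``V(times[0]) = v0`` at the given times.

    Adaptive integration (LSODA by default); tiny negative excursions are
    clipped to zero before fractional-power evaluation.  Unbounded growth
    past ``max_volume`` terminates integration cleanly: the returned
    trajectory has ``diverged=True`` and ``last_valid_time`` set, never a
    silent NaN or inf among the reported volumes.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a 1-D array with at least one entry")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must start at >= 0 days")
    if v0 <= 0:
        raise DomainError(f"initial volume must be > 0, got {v0}")

    c0 = chemo.c0 if chemo is not None else 0.0
    p = model.params
    name = model.name

    def fun(t: float, y):
        v = y[0] if y[0] > 0.0 else 0.0
        return (_raw_rhs(name, p, v) - c0 * v,)

    def blowup(t: float, y):
        return y[0] - max_volume

    blowup.terminal = True
    blowup.direction = 1

    if len(times) == 1:
        return Trajectory(times=times, volumes=np.array([v0]), diverged=False)

    sol = solve_ivp(
        fun,
        (times[0], times[-1]),
        [v0],
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
        events=blowup,
        dense_output=False,
    )
    vols = np.clip(sol.y[0], 0.0, None) if sol.y.size else np.empty(0)
    if sol.status == 0 and np.all(np.isfinite(vols)):
        return Trajectory(times=times, volumes=vols, diverged=False)
    # terminated by the blow-up event or solver failure
    last_t = float(sol.t_events[0][0]) if sol.status == 1 and len(sol.t_events[0]) else (
        float(sol.t[-1]) if len(sol.t) else float(times[0])
    )
    keep = np.isfinite(vols)
    return Trajectory(
        times=sol.t[keep],
        volumes=vols[keep],
        diverged=True,
        last_valid_time=last_t,
    )


def predict_volumes(
    model: GrowthModelSpec,
    v0: float,
    times: Sequence[float],
    chemo: ChemoSetting | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Model volumes at ``times`` (V = v0 at times[0]); (volumes, diverged).

    Uses the closed form when one exists and no chemotherapy is applied,
    otherwise the adaptive solver.  On divergence the returned array is
    padded with ``inf`` for the unreached times.
    """
    times = np.asarray(times, dtype=float)
    c0 = chemo.c0 if chemo is not None else 0.0
    if c0 == 0.0:
        try:
            vols = closed_form_volume(model, v0, times - times[0])
            vols = np.atleast_1d(np.asarray(vols, dtype=float))
            diverged = bool(np.any(~np.isfinite(vols)) or np.any(vols > DIVERGENCE_THRESHOLD))
            return vols, diverged
        except ClosedFormUnavailable:
            pass
    traj = solve_trajectory(model, v0, times, chemo, rtol=rtol, atol=atol)
    if not traj.diverged:
        return traj.volumes, False
    full = np.full(len(times), np.inf)
    full[: len(traj.volumes)] = traj.volumes
    return full, True
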