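"""Least-squares fitting of growth models and AICc model selection.

Fitting minimizes the sum of squared residuals

    SSR = sum_i (x_i - m_i)^2

between observed volumes ``x_i`` and model predictions ``m_i`` at the
observation times.  Optimization is a bounded truncated-Newton (TNC)
search over log-transformed parameters, multistarted from a seeded
Latin-hypercube, with a trust-region-reflective least-squares polish of
the best start.  The initial volume is fixed to the first observation by
default, so the free-parameter count K matches the model (1-3).

Small-sample model selection uses the corrected Akaike information
criterion

    AICc = n ln(SSR/n) + 2(K+1)n / (n - K - 2),

lower is better; ties are broken toward fewer parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.integrate import odeint
from scipy.stats import qmc

from .models import (
    MODEL_NAMES,
    PARAM_NAMES,
    ClosedFormUnavailable,
    DegenerateModelWarning,
    GrowthModelSpec,
    ParameterSet,
    closed_form_volume,
    predict_volumes,
)
from .models import DIVERGENCE_THRESHOLD, _raw_rhs

__all__ = [
    "TimeSeries",
    "FitConfig",
    "FitResult",
    "AICcUndefinedError",
    "compute_ssr",
    "compute_aicc",
    "fit_model",
    "select_model",
    "extrapolate_and_score",
]

_PENALTY = 1e30


class AICcUndefinedError(ValueError):
    """AICc requires n - K - 2 > 0."""


def _fit_predict(
    spec: GrowthModelSpec, v0: float, times: np.ndarray, rtol: float, atol: float
) -> tuple[np.ndarray, bool]:
    """Fit-time trajectory: closed form when available, else plain LSODA.

    Inside the optimizer loop the divergence-event machinery of
    :func:`oncofit.models.solve_trajectory` is unnecessary overhead (the
    bounded models cannot blow up and the unbounded ones are rejected by
    the finiteness check); ``scipy.integrate.odeint`` is several times
    faster per call.  Returns (volumes, bad) where ``bad`` flags any
    non-finite or beyond-threshold volume.
    """
    try:
        vols = np.atleast_1d(
            np.asarray(closed_form_volume(spec, v0, times - times[0]), float)
        )
    except ClosedFormUnavailable:
        name, p = spec.name, spec.params

        def f(v, t):
            return _raw_rhs(name, p, v[0] if v[0] > 0.0 else 0.0)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vols = odeint(
                f, [v0], times, rtol=rtol, atol=atol, mxstep=5000
            )[:, 0]
    bad = bool(
        np.any(~np.isfinite(vols)) or np.any(np.abs(vols) > DIVERGENCE_THRESHOLD)
    )
    return vols, bad


@dataclass
class TimeSeries:
    """Paired (time, volume) tumor observations.

    Times in days, strictly increasing; volumes in mm^3, positive.
    """

    times: np.ndarray
    volumes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape or self.times.ndim != 1:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a time series needs at least 2 observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_days": self.times, "volume_mm3": self.volumes}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "TimeSeries":
        df = pd.read_csv(path)
        missing = {"time_days", "volume_mm3"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            times=df["time_days"].to_numpy(float),
            volumes=df["volume_mm3"].to_numpy(float),
            label=label if label is not None else str(path),
        )


def default_bounds(name: str) -> dict[str, tuple[float, float]]:
    """Box bounds on the positive parameters, in natural units.

    Rate-like ``a`` is capped at 10/day, except for the linear and
    surface models where ``a`` carries volume units (late-phase growth
    in mm^3/day and mm^2-flavored units respectively; the per-day rate
    there is a/b or a/b^(1/3)) and plausible magnitudes reach the
    thousands.
    """
    if name == "linear":
        bounds = {"a": (1e-6, 1e4)}
    elif name == "surface":
        bounds = {"a": (1e-6, 1e3)}
    else:
        bounds = {"a": (1e-6, 10.0)}
    if name == "mendelsohn":
        bounds["b"] = (0.1, 3.0)
    elif name != "exponential":
        bounds["b"] = (1e-6, 1e6)
    if name == "gompertz":
        bounds["c"] = (1e-6, 1e6)
    return bounds


@dataclass
class FitConfig:
    """Knobs of the fitting procedure.

    ``n_starts`` multistart points (seeded Latin hypercube in log-parameter
    space, plus one data-driven heuristic start); ``residual_mode`` is
    "absolute" (SSR on raw volumes, the default) or "relative";
    ``fit_v0`` frees the initial volume as an extra parameter (K then
    increments).  Solver tolerances apply to fit-time trajectory
    evaluation.
    """

    models: tuple[str, ...] = MODEL_NAMES
    n_starts: int = 32
    seed: int = 0
    fit_v0: bool = False
    residual_mode: str = "absolute"
    rtol: float = 1e-7
    atol: float = 1e-9
    maxfun: int = 300
    bounds: dict | None = None

    def bounds_for(self, name: str) -> dict[str, tuple[float, float]]:
        b = default_bounds(name)
        if self.bounds and name in self.bounds:
            b.update({k: tuple(v) for k, v in self.bounds[name].items()})
        return b

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FitConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class FitResult:
    """Outcome of fitting one model to one series."""

    model: GrowthModelSpec
    v0: float
    ssr: float
    aicc: float
    n: int
    k: int
    converged: bool
    n_starts: int
    seed: int
    t0: float = 0.0
    t_end: float = 0.0
    label: str = ""

    @property
    def params(self) -> tuple[float, ...]:
        return self.model.params.as_tuple()


def compute_ssr(
    observed: TimeSeries,
    model: GrowthModelSpec,
    v0: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Eq.-style SSR of the model trajectory from ``V(t_0)=v0`` vs the data.

    A trajectory that diverges before the last observation scores
    ``+inf`` so optimizers reject the region.
    """
    pred, diverged = predict_volumes(
        model, v0, observed.times, rtol=rtol, atol=atol
    )
    if diverged or not np.all(np.isfinite(pred)):
        return math.inf
    resid = observed.volumes - pred
    return float(resid @ resid)


def compute_aicc(ssr: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: n ln(SSR/n) + 2(K+1)n/(n-K-2).

    ``ssr = 0`` (a perfect fit) returns ``-inf`` with a warning so perfect
    fits rank first deterministically; ``n - k - 2 <= 0`` raises
    :class:`AICcUndefinedError`.
    """
    if n - k - 2 <= 0:
        raise AICcUndefinedError(
            f"AICc undefined: n - K - 2 = {n - k - 2} must be positive (n={n}, K={k})"
        )
    if ssr < 0:
        raise ValueError(f"SSR must be >= 0, got {ssr}")
    if ssr == 0:
        warnings.warn("SSR is exactly 0; AICc reported as -inf", stacklevel=2)
        return -math.inf
    return n * math.log(ssr / n) + 2.0 * (k + 1) * n / (n - k - 2)


def _heuristic_start(name: str, observed: TimeSeries) -> dict[str, float]:
    t, x = observed.times, observed.volumes
    span = max(t[-1] - t[0], 1e-9)
    slope = math.log(x[-1] / x[0]) / span if x[-1] > x[0] else math.log(2.0) / span
    slope = max(slope, 1e-5)
    vmax = float(np.max(x))
    vmed = float(np.median(x))
    if name == "exponential":
        return {"a": slope}
    if name == "mendelsohn":
        return {"a": slope, "b": 0.9}
    if name == "logistic":
        return {"a": slope, "b": 2.0 * vmax}
    if name == "linear":
        return {"a": slope * vmed, "b": vmed}
    if name == "surface":
        return {"a": slope * vmed ** (1.0 / 3.0), "b": vmed}
    if name == "gompertz":
        b0 = 2.0 * vmax
        return {"a": slope / math.log(b0 / 1.0), "b": b0, "c": 1.0}
    if name == "bertalanffy":
        r = (2.0 * vmax) ** (-1.0 / 3.0)
        a0 = slope / (1.0 - r) if r < 0.9 else 2.0 * slope
        return {"a": a0, "b": a0 * r}
    raise AssertionError(name)


def _make_spec(name: str, values: Sequence[float]) -> GrowthModelSpec:
    names = PARAM_NAMES[name]
    kw = dict(zip(names, values))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateModelWarning)
        return GrowthModelSpec(name=name, params=ParameterSet(**kw))


def fit_model(
    observed: TimeSeries, name: str, config: FitConfig | None = None
) -> FitResult:
    """Fit one named model to a series by bounded multistart least squares.

    Deterministic given (data, config.seed, config.n_starts).  When all
    starts fail the result carries ``converged=False`` (SSR inf) rather
    than raising mid-pipeline.
    """
    config = config or FitConfig()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    t, x = observed.times, observed.volumes
    n = len(observed)
    pnames = list(PARAM_NAMES[name])
    bounds_nat = config.bounds_for(name)
    if config.fit_v0:
        pnames = pnames + ["v0"]
        bounds_nat = dict(bounds_nat)
        bounds_nat["v0"] = (x[0] * 0.1, x[0] * 10.0)
    k_ode = len(PARAM_NAMES[name])
    k = len(pnames)
    lb = np.log([bounds_nat[p][0] for p in pnames])
    ub = np.log([bounds_nat[p][1] for p in pnames])
    relative = config.residual_mode == "relative"

    def residuals(theta: np.ndarray) -> np.ndarray:
        vals = np.exp(np.clip(theta, lb, ub))
        if config.fit_v0:
            spec = _make_spec(name, vals[:-1])
            v0 = float(vals[-1])
        else:
            spec = _make_spec(name, vals)
            v0 = float(x[0])
        pred, bad = _fit_predict(spec, v0, t, config.rtol, config.atol)
        if bad:
            return np.full(n, math.sqrt(_PENALTY / n))
        r = x - pred
        if relative:
            r = r / x
        return r

    def objective(theta: np.ndarray) -> float:
        r = residuals(theta)
        return float(r @ r)

    # multistart: data-driven heuristic + seeded Latin hypercube in log space
    heur = _heuristic_start(name, observed)
    if config.fit_v0:
        heur["v0"] = float(x[0])
    th0 = np.log(
        [np.clip(heur[p], bounds_nat[p][0], bounds_nat[p][1]) for p in pnames]
    )
    starts = [th0]
    n_lhs = max(config.n_starts - 1, 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=k, seed=config.seed)
        unit = sampler.random(n_lhs)
        starts.extend(list(lb + unit * (ub - lb)))

    best_theta, best_val, any_ok = th0, math.inf, False
    for theta in starts:
        res = optimize.minimize(
            objective,
            theta,
            method="TNC",
            bounds=list(zip(lb, ub)),
            options={"maxfun": config.maxfun},
        )
        val = objective(res.x)
        if math.isfinite(val) and val < _PENALTY / 2:
            any_ok = True
        if val < best_val:
            best_val, best_theta = val, res.x

    if any_ok:
        # trust-region-reflective polish of the best start
        polish = optimize.least_squares(
            residuals, best_theta, bounds=(lb, ub), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-12,
        )
        if objective(polish.x) <= best_val:
            best_theta, best_val = polish.x, objective(polish.x)

    vals = [float(v) for v in np.exp(np.clip(best_theta, lb, ub))]
    if config.fit_v0:
        spec = _make_spec(name, vals[:-1])
        v0 = float(vals[-1])
    else:
        spec = _make_spec(name, vals)
        v0 = float(x[0])
    # report the literal (absolute) SSR at tight solver tolerance
    ssr = compute_ssr(observed, spec, v0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aicc = compute_aicc(ssr, n, k) if math.isfinite(ssr) else math.inf
    except AICcUndefinedError:
        aicc = math.nan
    return FitResult(
        model=spec,
        v0=v0,
        ssr=ssr,
        aicc=aicc,
        n=n,
        k=k,
        converged=any_ok and math.isfinite(ssr),
        n_starts=config.n_starts,
        seed=config.seed,
        t0=float(t[0]),
        t_end=float(t[-1]),
        label=observed.label,
    )


def select_model(fits: Sequence[FitResult]) -> tuple[str, pd.DataFrame]:
    """Pick the model with the lowest AICc; ties go to fewer parameters.

    All fits must share the same n (same data).  Returns the winning
    model name and the full ranking table.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least 2 fits")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits compare different data sizes n={sorted(ns)}")
    usable = [f for f in fits if not math.isnan(f.aicc)]
    if not usable:
        raise ValueError("no fit has a defined AICc")
    best_aicc = min(f.aicc for f in usable)
    contenders = [f for f in usable if f.aicc - best_aicc < 1e-9]
    winner = min(contenders, key=lambda f: f.k)
    table = pd.DataFrame(
        {
            "model": [f.model.name for f in fits],
            "k": [f.k for f in fits],
            "ssr": [f.ssr for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.aicc - best_aicc for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values(["aicc", "k"], na_position="last").reset_index(drop=True)
    return winner.model.name, table


def extrapolate_and_score(fit: FitResult, heldout: TimeSeries) -> float:
    """Prediction SSR of a fitted model on strictly later held-out points.

    Integrates the fitted model from its fitted (t0, v0) across the full
    horizon and scores squared error on the held-out points only;
    divergence before the last held-out time scores ``+inf``.
    """
    if heldout.times[0] <= fit.t_end:
        raise ValueError(
            "held-out times must all be later than the fitted series' last time"
        )
    times = np.concatenate(([fit.t0], heldout.times))
    pred, diverged = predict_volumes(fit.model, fit.v0, times)
    if diverged or not np.all(np.isfinite(pred)):
        return math.inf
    resid = heldout.volumes - pred[1:]
    return float(resid @ resid)
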