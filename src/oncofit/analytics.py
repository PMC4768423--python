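"""Closed-form clinical quantities of the seven growth models.

For each model, with and without constant-concentration chemotherapy
(kill term ``c0*V``), this module derives:

* the fixed points of the ODE with a numeric stability label,
* the maximum tumor size (the nonzero stable fixed point, or unbounded),
* the doubling time ``DT = ln2 / lambda`` where ``lambda`` is the
  initial growth rate obtained by expanding the right-hand side about
  ``V = 0`` (for the fractional-power mendelsohn and bertalanffy models
  the expansion is singular and ``lambda`` is the conventional relative
  growth rate at unit volume, a - b for bertalanffy and a for
  mendelsohn — flagged via ``caveats``),
* the growth condition ``lambda > 0``,
* the minimum constant chemotherapy concentration that suppresses the
  tumor, i.e. a kill rate equal to the initial growth rate.

Untreated, four models (exponential, mendelsohn, linear, surface) grow
without bound; under any positive kill rate only the exponential model
remains unbounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import (
    ChemoSetting,
    GrowthModelSpec,
    rhs_eval,
)

__all__ = [
    "FixedPoint",
    "ClinicalPredictions",
    "GrowthConditionError",
    "UNBOUNDED",
    "fixed_points",
    "max_tumor_size",
    "initial_growth_rate",
    "doubling_time",
    "growth_condition",
    "min_cure_concentration",
]

#: Sentinel for an unbounded maximum tumor size.
UNBOUNDED = math.inf

LN2 = math.log(2.0)


class GrowthConditionError(ValueError):
    """Requested quantity is undefined because the tumor does not grow."""


@dataclass(frozen=True)
class FixedPoint:
    """A non-negative root of dV/dt = 0 with a numeric stability label."""

    volume: float  # mm^3; math.inf marks the unbounded attractor
    stable: bool


def initial_growth_rate(model: GrowthModelSpec) -> float:
    """The rate ``lambda`` governing early growth (per day).

    exponential/mendelsohn/logistic: a; linear: a/b; surface: a/b^(1/3);
    gompertz: a ln(b/c); bertalanffy: a - b.
    """
    p = model.params
    name = model.name
    if name in ("exponential", "mendelsohn", "logistic"):
        return p.a
    if name == "linear":
        return p.a / p.b
    if name == "surface":
        return p.a / p.b ** (1.0 / 3.0)
    if name == "gompertz":
        return p.a * math.log(p.b / p.c)
    if name == "bertalanffy":
        return p.a - p.b
    raise AssertionError(name)


def growth_condition(model: GrowthModelSpec) -> bool:
    """True iff a nascent tumor grows (initial growth rate positive)."""
    return bool(initial_growth_rate(model) > 0.0)


def doubling_time(model: GrowthModelSpec) -> float:
    """Early-phase doubling time DT = ln2 / lambda, in days."""
    lam = initial_growth_rate(model)
    if lam <= 0:
        raise GrowthConditionError(
            f"{model.name}: initial growth rate {lam:.4g}/day is not positive; "
            "the tumor does not grow and no doubling time is defined"
        )
    return LN2 / lam


def min_cure_concentration(model: GrowthModelSpec) -> float:
    """Smallest constant kill rate C0 (per day) that suppresses the tumor.

    Equals the initial growth rate; 0 when the tumor does not grow
    (no drug needed).
    """
    return max(initial_growth_rate(model), 0.0)


def _nonzero_fixed_point(model: GrowthModelSpec, c0: float) -> float:
    """Algebraic nonzero root of the (treated) RHS; may be inf or negative."""
    p = model.params
    name = model.name
    if name == "exponential":
        return UNBOUNDED
    if name == "mendelsohn":
        if c0 == 0.0:
            return UNBOUNDED
        return (c0 / p.a) ** (1.0 / (p.b - 1.0)) if p.b != 1.0 else UNBOUNDED
    if name == "logistic":
        return p.b * (p.a - c0) / p.a
    if name == "linear":
        return UNBOUNDED if c0 == 0.0 else p.a / c0 - p.b
    if name == "surface":
        # algebraic root of aV/(V+b)^(1/3) = c0 V; consistent with the
        # cure condition c0 = a/b^(1/3) vanishing at V* = 0
        return UNBOUNDED if c0 == 0.0 else (p.a / c0) ** 3 - p.b
    if name == "gompertz":
        return p.b * math.exp(-c0 / p.a) - p.c
    if name == "bertalanffy":
        return (p.a / (p.b + c0)) ** 3
    raise AssertionError(name)


def _sign_at(model: GrowthModelSpec, chemo: ChemoSetting, v: float) -> float:
    return rhs_eval(model, v, chemo)


def fixed_points(
    model: GrowthModelSpec, chemo: ChemoSetting | None = None
) -> list[FixedPoint]:
    """The non-negative fixed points of the (treated) model.

    Always contains V = 0; the second entry is the nonzero root — a
    finite volume, or ``inf`` when no positive finite root exists and
    trajectories grow without bound.  A nonzero algebraic root that is
    not positive (over-suppression) collapses onto 0 and only the zero
    fixed point is returned.  Stability is classified by sign-checking
    the RHS on either side of each root rather than via symbolic
    derivatives, which is uniform across the fractional-power models.
    """
    chemo = chemo or ChemoSetting(0.0)
    c0 = chemo.c0
    star = _nonzero_fixed_point(model, c0)

    pts: list[FixedPoint] = []
    # scale for probing around V=0
    scale = star if (math.isfinite(star) and star > 0) else 1.0
    eps = max(scale * 1e-6, 1e-12)
    zero_stable = _sign_at(model, chemo, eps) < 0
    pts.append(FixedPoint(0.0, zero_stable))

    if not math.isfinite(star):
        probe = 1e9 * max(1.0, *(p for p in model.params.as_tuple()))
        pts.append(FixedPoint(UNBOUNDED, _sign_at(model, chemo, probe) > 0))
    elif star > 0:
        lo = _sign_at(model, chemo, star * (1.0 - 1e-4))
        hi = _sign_at(model, chemo, star * (1.0 + 1e-4))
        pts.append(FixedPoint(star, lo > 0 and hi < 0))
    return pts


def max_tumor_size(
    model: GrowthModelSpec, chemo: ChemoSetting | None = None
) -> float:
    """Maximum predicted tumor size (mm^3), ``inf`` when unbounded.

    Untreated: inf for exponential/mendelsohn/linear/surface, b for
    logistic, b - c for gompertz, (a/b)^3 for bertalanffy.  Treated:
    the nonzero fixed point of the RHS minus ``c0*V``; a non-positive
    value is reported as 0 (tumor eradicated).  A treated exponential
    model is unbounded whenever c0 < a, else eradicated.
    """
    c0 = chemo.c0 if chemo is not None else 0.0
    if model.name == "exponential":
        return UNBOUNDED if model.params.a > c0 else 0.0
    star = _nonzero_fixed_point(model, c0)
    if not math.isfinite(star):
        return UNBOUNDED
    return max(star, 0.0)


@dataclass(frozen=True)
class ClinicalPredictions:
    """Clinically relevant quantities for one parameterized model.

    ``max_size`` may be ``inf`` (unbounded growth); ``doubling_time`` is
    None when the growth condition fails.  ``caveats`` records
    convention flags (e.g. the bertalanffy/mendelsohn cure thresholds
    are unit-volume conventions: the fractional-power term dominates any
    linear kill term near V = 0, so V = 0 is not linearly stabilized).
    """

    model_name: str
    max_size: float
    doubling_time: float | None
    growth_condition_met: bool
    min_cure_concentration: float
    eradicated: bool = False
    caveats: tuple[str, ...] = ()

    @classmethod
    def from_model(
        cls, model: GrowthModelSpec, chemo: ChemoSetting | None = None
    ) -> "ClinicalPredictions":
        grows = growth_condition(model)
        size = max_tumor_size(model, chemo)
        caveats: list[str] = []
        if model.name == "bertalanffy":
            caveats.append(
                "cure threshold a-b is the unit-volume convention; V=0 is "
                "never linearly stable for a>0"
            )
        if model.name == "mendelsohn" and model.params.b != 1.0:
            caveats.append(
                "cure threshold a is the unit-volume convention for b != 1"
            )
        return cls(
            model_name=model.name,
            max_size=float(size),
            doubling_time=float(doubling_time(model)) if grows else None,
            growth_condition_met=grows,
            min_cure_concentration=float(min_cure_concentration(model)),
            eradicated=bool(size == 0.0),
            caveats=tuple(caveats),
        )

    def to_record(self) -> dict:
        """Flat JSON/CSV-friendly record; unbounded size serialized as a string."""
        return {
            "model": self.model_name,
            "max_size_mm3": "unbounded" if math.isinf(self.max_size) else self.max_size,
            "doubling_time_days": self.doubling_time,
            "growth_condition_met": self.growth_condition_met,
            "min_cure_concentration_per_day": self.min_cure_concentration,
            "eradicated": self.eradicated,
            "caveats": "; ".join(self.caveats),
        }
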