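"""Synthetic xenograft-like tumor-volume time series with known truth.

Emulates the design of a long subcutaneous-xenograft growth experiment:
sigmoidal growth from a small initial volume, 7-14 irregularly spaced
caliper measurements spanning up to ~114 days, multiplicative
(lognormal, mean-1) measurement noise whose magnitude scales with tumor
size.  Every series carries a ground-truth record (true parameters and
the true clinical predictions), so the whole fit/extrapolate/predict
pipeline can be validated end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .analytics import ClinicalPredictions, growth_condition
from .fitting import TimeSeries
from .models import GrowthModelSpec, solve_trajectory

__all__ = [
    "NoiseConfig",
    "StudyDesign",
    "GroundTruth",
    "DivergenceError",
    "generate_series",
    "truncate_series",
    "DEMO_TRUTH",
    "DEMO_V0",
    "RECOVERY_TRUTHS",
]

#: Default demo truth: a gompertz tumor qualitatively like a GI-101A
#: xenograft control curve — slow early growth (early doubling time
#: ~12 d), inflection near day 91 so the curve is still rising at day
#: 114, and final volumes in the low thousands of mm^3.  These are
#: illustrative values, not literature estimates.
DEMO_TRUTH = GrowthModelSpec.create("gompertz", a=0.015, b=5000.0, c=1.0)
DEMO_V0 = 100.0

#: Per-model ground truths used for parameter-recovery exercises.
#: Chosen so every parameter is identifiable from a 14-point/114-day
#: series (e.g. the gompertz offset c is only identifiable when the
#: early volumes are comparable to c).
RECOVERY_TRUTHS: dict[str, tuple[GrowthModelSpec, float]] = {
    "exponential": (GrowthModelSpec.create("exponential", a=0.04), 50.0),
    "mendelsohn": (GrowthModelSpec.create("mendelsohn", a=0.3, b=0.7), 50.0),
    "logistic": (GrowthModelSpec.create("logistic", a=0.1, b=6000.0), 50.0),
    "linear": (GrowthModelSpec.create("linear", a=60.0, b=700.0), 50.0),
    "surface": (GrowthModelSpec.create("surface", a=0.8, b=500.0), 50.0),
    "gompertz": (GrowthModelSpec.create("gompertz", a=0.1, b=6000.0, c=150.0), 20.0),
    "bertalanffy": (GrowthModelSpec.create("bertalanffy", a=1.0, b=0.05), 50.0),
}


class DivergenceError(RuntimeError):
    """The ground-truth model diverges before the requested horizon."""


@dataclass(frozen=True)
class NoiseConfig:
    """Multiplicative lognormal measurement noise.

    ``cv`` is the coefficient of variation (0 gives exact model curves);
    the lognormal is parameterized to have mean 1, so noise is unbiased.
    ``floor`` is the smallest reportable volume (mm^3).
    """

    cv: float = 0.1
    seed: int = 0
    floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.floor < 0:
            raise ValueError(f"floor must be >= 0, got {self.floor}")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the emulated experiment.

    Defaults mirror a long xenograft study: 14 points spanning 114 days
    with the first half (7 points) in the early growth phase; interior
    times jittered by up to 10% of the nominal spacing.
    """

    n_points: int = 14
    horizon: float = 114.0
    spacing: str = "jittered"
    truncation_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation_fraction must be in (0, 1)")
        if self.spacing not in ("uniform", "jittered"):
            raise ValueError(f"spacing must be uniform or jittered, got {self.spacing}")


@dataclass(frozen=True)
class GroundTruth:
    """True generating model and its clinical predictions for one series."""

    model: GrowthModelSpec
    v0: float
    predictions: ClinicalPredictions
    design: StudyDesign
    noise: NoiseConfig
    note: str = "synthetic series; parameters are illustrative, not literature values"

    def to_json(self, path: str | Path) -> None:
        rec = {
            "model": self.model.name,
            "params": dict(
                zip(("a", "b", "c"), self.model.params.as_tuple())
            ),
            "v0_mm3": self.v0,
            "predictions": self.predictions.to_record(),
            "design": asdict(self.design),
            "noise": asdict(self.noise),
            "note": self.note,
        }
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))


def _sample_times(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    times = np.linspace(0.0, design.horizon, design.n_points)
    if design.spacing == "jittered":
        dt = design.horizon / (design.n_points - 1)
        jitter = rng.uniform(-0.1, 0.1, design.n_points) * dt
        jitter[0] = jitter[-1] = 0.0  # keep the endpoints anchored
        times = times + jitter
    return times


def generate_series(
    truth: GrowthModelSpec,
    v0: float,
    design: StudyDesign | None = None,
    noise: NoiseConfig | None = None,
    label: str = "synthetic",
) -> tuple[TimeSeries, GroundTruth]:
    """Simulate one noisy series from a known model.

    Reproducible given ``noise.seed``; ``cv = 0`` returns the exact
    model curve at the sampled times.
    """
    design = design or StudyDesign()
    noise = noise or NoiseConfig()
    if v0 <= 0:
        raise ValueError(f"v0 must be > 0, got {v0}")
    if not growth_condition(truth):
        raise ValueError(
            f"{truth.name}: growth condition not met; the synthetic tumor would not grow"
        )
    rng = np.random.default_rng(noise.seed)
    times = _sample_times(design, rng)
    traj = solve_trajectory(truth, v0, times)
    if traj.diverged:
        raise DivergenceError(
            f"{truth.name} diverges at t={traj.last_valid_time:.3g} d before the "
            f"{design.horizon} d horizon; use a shorter horizon"
        )
    curve = traj.volumes
    if noise.cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.cv ** 2))
        factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, design.n_points))
        volumes = curve * factors
    else:
        volumes = curve.copy()
    volumes = np.maximum(volumes, noise.floor)
    series = TimeSeries(times=times, volumes=volumes, label=label)
    gt = GroundTruth(
        model=truth,
        v0=v0,
        predictions=ClinicalPredictions.from_model(truth),
        design=design,
        noise=noise,
    )
    return series, gt


def truncate_series(
    series: TimeSeries, design: StudyDesign | float | None = None
) -> tuple[TimeSeries, TimeSeries]:
    """Split a series into early and late halves, order preserved.

    The early subset holds the first ``ceil(fraction * n)`` points;
    early + late partition the original.  A fraction leaving either side
    empty is a design error.
    """
    if isinstance(design, StudyDesign):
        fraction = design.truncation_fraction
    elif design is None:
        fraction = 0.5
    else:
        fraction = float(design)
    if not 0.0 < fraction < 1.0:
        raise ValueError("truncation fraction must be in (0, 1)")
    n = len(series)
    n_early = math.ceil(fraction * n)
    if n_early < 2 or n - n_early < 2:
        raise ValueError(
            f"fraction {fraction} on {n} points leaves early={n_early}, "
            f"late={n - n_early}; both subsets need at least 2 points"
        )
    early = TimeSeries(
        times=series.times[:n_early],
        volumes=series.volumes[:n_early],
        label=f"{series.label}[early]",
    )
    late = TimeSeries(
        times=series.times[n_early:],
        volumes=series.volumes[n_early:],
        label=f"{series.label}[late]",
    )
    return early, late
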