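"""Full model-comparison experiment: truncated fits, extrapolation, and
clinical predictions.

The experiment mirrors common practice with xenograft growth curves:
fit every growth model to the early half of a series, use the fitted
parameters to extrapolate the held-out later half (scored by prediction
SSR), then refit on the full series and compare the clinically relevant
quantities — maximum tumor size, doubling time, and minimum
chemotherapy concentration for suppression — between the two fits.
The report records, per criterion, which model "wins" (lowest fit SSR,
lowest AICc, lowest prediction SSR); these can be three different
models.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .analytics import ClinicalPredictions
from .fitting import (
    FitConfig,
    FitResult,
    TimeSeries,
    extrapolate_and_score,
    fit_model,
    select_model,
)
from .synthetic import StudyDesign, truncate_series

__all__ = [
    "ModelRow",
    "ComparisonReport",
    "run_comparison",
    "percent_change",
    "fold_spread",
]

_QUANTITIES = ("max_size", "doubling_time", "min_cure_concentration")


def percent_change(truncated_value: float, full_value: float) -> float | None:
    """100 * (full - truncated) / truncated; None when not applicable.

    An unbounded (inf) or undefined (NaN/None) value on either side, or
    a zero denominator, yields None rather than NaN.
    """
    for v in (truncated_value, full_value):
        if v is None or not math.isfinite(v):
            return None
    if truncated_value == 0:
        return None
    return 100.0 * (full_value - truncated_value) / truncated_value


def fold_spread(values: Sequence[float]) -> float:
    """max/min over the finite positive entries of ``values``.

    Entries from unbounded or non-growing models (inf, NaN, None, <= 0)
    are excluded; fewer than 2 usable entries is an error.
    """
    finite = [
        float(v)
        for v in values
        if v is not None and math.isfinite(v) and v > 0
    ]
    if len(finite) < 2:
        raise ValueError(
            f"fold spread needs >= 2 finite positive values, got {len(finite)}"
        )
    return max(finite) / min(finite)


@dataclass
class ModelRow:
    """Per-model results for one subset (truncated or full)."""

    model: str
    params: dict
    v0: float
    converged: bool
    ssr_fit: float
    aicc: float
    ssr_prediction: float | None  # truncated fits only
    max_size: float  # inf = unbounded
    doubling_time: float | None
    min_cure_concentration: float
    growth_condition_met: bool
    notes: str = ""

    @classmethod
    def from_fit(
        cls, fit: FitResult, ssr_prediction: float | None = None
    ) -> "ModelRow":
        preds = ClinicalPredictions.from_model(fit.model)
        notes = []
        if not fit.converged:
            notes.append("fit did not converge")
        if not preds.growth_condition_met:
            notes.append("growth condition not met; excluded from spreads")
        if math.isinf(preds.max_size):
            notes.append("unbounded maximum size; excluded from size spread")
        notes.extend(preds.caveats)
        return cls(
            model=fit.model.name,
            params=dict(
                zip(("a", "b", "c"), (float(p) for p in fit.params))
            ),
            v0=fit.v0,
            converged=fit.converged,
            ssr_fit=fit.ssr,
            aicc=fit.aicc,
            ssr_prediction=ssr_prediction,
            max_size=preds.max_size,
            doubling_time=preds.doubling_time,
            min_cure_concentration=preds.min_cure_concentration,
            growth_condition_met=preds.growth_condition_met,
            notes="; ".join(notes),
        )


def _jsonable(x):
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if math.isinf(x):
            return "unbounded" if x > 0 else "-unbounded"
        if math.isnan(x):
            return None
    return x


@dataclass
class ComparisonReport:
    """Everything the experiment computed, per model and per subset."""

    label: str
    seed: int
    truncation_fraction: float
    rows: dict  # {"truncated": [ModelRow...], "full": [ModelRow...]}
    percent_changes: dict  # {model: {quantity: pct or None}}
    selections: dict  # {"lowest_ssr": name, "lowest_aicc": name, "lowest_prediction_ssr": name}
    fold_spreads: dict  # {subset: {quantity: ratio or None}}
    notes: list = field(default_factory=list)

    def to_frame(self, subset: str) -> pd.DataFrame:
        recs = []
        for row in self.rows[subset]:
            d = asdict(row)
            d.update({f"param_{k}": v for k, v in d.pop("params").items()})
            recs.append(d)
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return _jsonable(obj)

        return clean(
            {
                "label": self.label,
                "seed": self.seed,
                "truncation_fraction": self.truncation_fraction,
                "rows": {
                    subset: [asdict(r) for r in rows]
                    for subset, rows in self.rows.items()
                },
                "percent_changes": self.percent_changes,
                "selections": self.selections,
                "fold_spreads": self.fold_spreads,
                "notes": self.notes,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        if fmt == "csv":
            for subset in self.rows:
                self.to_frame(subset).to_csv(
                    out / f"fits_{subset}.csv", index=False
                )


def run_comparison(
    data: TimeSeries,
    design: StudyDesign | None = None,
    config: FitConfig | None = None,
) -> ComparisonReport:
    """Run the full truncate/fit/extrapolate/refit experiment on one series.

    Deterministic given (data, config.seed).  A model whose fit fails is
    flagged in its row; the report is still produced.
    """
    design = design or StudyDesign()
    config = config or FitConfig()
    if len(data) < 6:
        raise ValueError("the comparison needs at least 6 observations")
    early, late = truncate_series(data, design)

    rows_trunc: list[ModelRow] = []
    rows_full: list[ModelRow] = []
    fits_trunc: list[FitResult] = []
    for name in config.models:
        fit_early = fit_model(early, name, config)
        try:
            pred_ssr = extrapolate_and_score(fit_early, late)
        except ValueError:
            pred_ssr = math.inf
        fit_full = fit_model(data, name, config)
        fits_trunc.append(fit_early)
        rows_trunc.append(ModelRow.from_fit(fit_early, pred_ssr))
        rows_full.append(ModelRow.from_fit(fit_full))

    pct = {
        rt.model: {
            "max_size": percent_change(rt.max_size, rf.max_size),
            "doubling_time": percent_change(
                rt.doubling_time if rt.doubling_time is not None else math.nan,
                rf.doubling_time if rf.doubling_time is not None else math.nan,
            ),
            "min_cure_concentration": percent_change(
                rt.min_cure_concentration, rf.min_cure_concentration
            ),
        }
        for rt, rf in zip(rows_trunc, rows_full)
    }

    conv = [r for r in rows_trunc if r.converged]
    selections = {}
    if conv:
        selections["lowest_ssr"] = min(conv, key=lambda r: r.ssr_fit).model
        aicc_name, _ = select_model(fits_trunc)
        selections["lowest_aicc"] = aicc_name
        selections["lowest_prediction_ssr"] = min(
            conv, key=lambda r: (r.ssr_prediction is None, r.ssr_prediction)
        ).model

    notes: list[str] = []

    def _spread(rows: list[ModelRow], attr: str) -> float | None:
        vals = [getattr(r, attr) for r in rows if r.converged]
        try:
            return fold_spread(vals)
        except ValueError as exc:
            notes.append(f"{attr}: {exc}")
            return None

    spreads = {
        subset: {
            "max_size": _spread(rows, "max_size"),
            "doubling_time": _spread(rows, "doubling_time"),
            "min_cure_concentration": _spread(rows, "min_cure_concentration"),
        }
        for subset, rows in (("truncated", rows_trunc), ("full", rows_full))
    }

    return ComparisonReport(
        label=data.label,
        seed=config.seed,
        truncation_fraction=design.truncation_fraction,
        rows={"truncated": rows_trunc, "full": rows_full},
        percent_changes=pct,
        selections=selections,
        fold_spreads=spreads,
        notes=notes,
    )
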