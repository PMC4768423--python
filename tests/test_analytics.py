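"""Fixed points, maximum sizes, doubling times, and cure thresholds.

The closed-form quantities are cross-checked against independent
brute-force oracles: bracketed root-finding on the right-hand side for
fixed points, and direct integration for the cure-threshold behavior.
"""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from oncofit.analytics import (
    UNBOUNDED,
    ClinicalPredictions,
    GrowthConditionError,
    doubling_time,
    fixed_points,
    growth_condition,
    initial_growth_rate,
    max_tumor_size,
    min_cure_concentration,
)
from oncofit.models import (
    MODEL_NAMES,
    ChemoSetting,
    GrowthModelSpec,
    rhs_eval,
    solve_trajectory,
)

from conftest import draw_spec

UNBOUNDED_UNTREATED = {"exponential", "mendelsohn", "linear", "surface"}


def root_oracle(model, c0):
    """Independent nonzero root of the treated RHS via sign-scan + brentq."""
    chemo = ChemoSetting(c0)

    def f(v):
        return rhs_eval(model, v, chemo)

    grid = np.geomspace(1e-8, 1e10, 600)
    vals = np.array([f(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[-1]
    return brentq(f, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-14)


# ---------------------------------------------------------------- fixed points


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_untreated_models_have_two_fixed_points_including_zero(name, rng):
    for _ in range(20):
        model = draw_spec(name, rng)
        pts = fixed_points(model)
        assert len(pts) == 2
        assert pts[0].volume == 0.0
        assert not pts[0].stable  # growth condition holds for these draws
        if name in UNBOUNDED_UNTREATED:
            assert math.isinf(pts[1].volume)
        else:
            assert math.isfinite(pts[1].volume) and pts[1].volume > 0
            assert pts[1].stable


def test_logistic_fixed_points_example():
    pts = fixed_points(GrowthModelSpec.create("logistic", a=1.0, b=100.0))
    assert [(p.volume, p.stable) for p in pts] == [(0.0, False), (100.0, True)]


def test_bertalanffy_fixed_point_is_cubed_ratio():
    pts = fixed_points(GrowthModelSpec.create("bertalanffy", a=2.0, b=1.0))
    assert pts[1].volume == pytest.approx(8.0, rel=1e-12)
    assert pts[1].stable


def test_surface_treated_fixed_point_example():
    pts = fixed_points(
        GrowthModelSpec.create("surface", a=1.0, b=8.0), ChemoSetting(0.25)
    )
    assert {round(p.volume, 9) for p in pts} == {0.0, 56.0}


def test_nonzero_fixed_points_are_roots_of_the_rhs(rng):
    for name in MODEL_NAMES:
        model = draw_spec(name, rng)
        for p in fixed_points(model):
            if math.isfinite(p.volume) and p.volume > 0:
                scale = abs(rhs_eval(model, p.volume * 1.5)) + 1e-12
                assert abs(rhs_eval(model, p.volume)) <= 1e-9 * max(scale, 1.0)


# ------------------------------------------------------------ maximum size


@pytest.mark.parametrize(
    "name,kw,c0,expected",
    [
        ("gompertz", dict(a=1.0, b=10.0, c=1.0), 0.0, 9.0),
        ("logistic", dict(a=1.0, b=100.0), 0.0, 100.0),
        ("bertalanffy", dict(a=2.0, b=1.0), 0.0, 8.0),
        ("linear", dict(a=10.0, b=2.0), 1.0, 8.0),
        ("logistic", dict(a=1.0, b=100.0), 1.0, 0.0),  # kill rate = a: eradicated
        ("surface", dict(a=1.0, b=8.0), 0.25, 56.0),
        ("gompertz", dict(a=1.0, b=10.0, c=1.0), 1.0, 10.0 / math.e - 1.0),
        ("mendelsohn", dict(a=0.5, b=0.5), 0.125, 16.0),  # (c0/a)^(1/(b-1))
        ("bertalanffy", dict(a=2.0, b=0.5), 0.5, 8.0),  # (a/(b+c0))^3
        ("exponential", dict(a=1.0), 0.5, UNBOUNDED),
        ("exponential", dict(a=1.0), 2.0, 0.0),  # over-suppressed
    ],
)
def test_max_tumor_size_table_values(name, kw, c0, expected):
    model = GrowthModelSpec.create(name, **kw)
    assert max_tumor_size(model, ChemoSetting(c0)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("name", sorted(UNBOUNDED_UNTREATED))
def test_untreated_unbounded_models(name, rng):
    model = draw_spec(name, rng)
    assert math.isinf(max_tumor_size(model))


def test_treated_formulas_reduce_to_untreated_at_vanishing_kill_rate(rng):
    tiny = ChemoSetting(1e-9)
    for name in MODEL_NAMES:
        model = draw_spec(name, rng)
        untreated = max_tumor_size(model)
        treated = max_tumor_size(model, tiny)
        if math.isinf(untreated):
            assert math.isinf(treated) or treated > 1e9
        else:
            assert treated == pytest.approx(untreated, rel=1e-4)


def test_treated_fixed_points_match_root_oracle(rng):
    """Every finite nonzero maximum size is the root-found zero of the RHS."""
    for name in MODEL_NAMES:
        for _ in range(20):
            model = draw_spec(name, rng)
            c0 = 0.5 * min_cure_concentration(model)
            if c0 <= 0:
                continue
            star = max_tumor_size(model, ChemoSetting(c0))
            if not math.isfinite(star) or star <= 0:
                continue
            oracle = root_oracle(model, c0)
            assert oracle is not None
            assert star == pytest.approx(oracle, rel=1e-9)


# ----------------------------------------------- doubling time & growth rate


@pytest.mark.parametrize(
    "name,kw,expected",
    [
        ("exponential", dict(a=math.log(2)), 1.0),
        ("mendelsohn", dict(a=math.log(2), b=0.5), 1.0),
        ("logistic", dict(a=math.log(2), b=100.0), 1.0),
        ("linear", dict(a=2.0, b=4.0), 2.0 * math.log(2)),
        ("surface", dict(a=1.0, b=8.0), 2.0 * math.log(2)),
        ("gompertz", dict(a=1.0, b=math.e, c=1.0), math.log(2)),
        ("bertalanffy", dict(a=2.0, b=1.0), math.log(2)),
    ],
)
def test_doubling_time_table_values(name, kw, expected):
    assert doubling_time(GrowthModelSpec.create(name, **kw)) == pytest.approx(
        expected, rel=1e-12
    )


def test_doubling_time_requires_growth():
    shrinking = GrowthModelSpec.create("bertalanffy", a=1.0, b=2.0)
    assert not growth_condition(shrinking)
    with pytest.raises(GrowthConditionError):
        doubling_time(shrinking)


@pytest.mark.parametrize(
    "name,kw,expected",
    [
        ("bertalanffy", dict(a=1.0, b=2.0), False),
        ("gompertz", dict(a=1.0, b=2.0, c=1.0), True),
        ("gompertz", dict(a=1.0, b=1.0, c=2.0), False),  # b < c
        ("logistic", dict(a=0.3, b=10.0), True),
    ],
)
def test_growth_condition(name, kw, expected):
    assert growth_condition(GrowthModelSpec.create(name, **kw)) is expected


@pytest.mark.parametrize(
    "name,kw,expected",
    [
        ("logistic", dict(a=0.5, b=123.0), 0.5),
        ("bertalanffy", dict(a=1.0, b=1.0), 0.0),  # a = b: nothing to cure
        ("surface", dict(a=1.0, b=8.0), 0.5),
        ("linear", dict(a=10.0, b=2.0), 5.0),
        ("gompertz", dict(a=0.5, b=math.e, c=1.0), 0.5),
    ],
)
def test_min_cure_concentration_table_values(name, kw, expected):
    assert min_cure_concentration(
        GrowthModelSpec.create(name, **kw)
    ) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_cure_threshold_equals_rate_recovered_from_doubling_time(name, rng):
    """DT and the cure threshold are two views of the same initial rate."""
    for _ in range(20):
        model = draw_spec(name, rng)
        lam = math.log(2) / doubling_time(model)
        assert min_cure_concentration(model) == pytest.approx(lam, rel=1e-12)
        assert initial_growth_rate(model) == pytest.approx(lam, rel=1e-12)


# ------------------------------------------------------- cure threshold check


def final_volume(model, c0, v0, horizon, n=60):
    traj = solve_trajectory(model, v0, np.linspace(0, horizon, n), ChemoSetting(c0))
    assert not traj.diverged
    return float(traj.volumes[-1])


def test_surface_cure_threshold_brackets_decay_and_growth():
    model = GrowthModelSpec.create("surface", a=1.0, b=8.0)  # threshold 0.5
    horizon = 200.0
    assert final_volume(model, 0.55, 1.0, horizon) < 0.5
    assert final_volume(model, 0.45, 1.0, horizon) > 2.0


def test_clinical_predictions_record_serialization():
    preds = ClinicalPredictions.from_model(
        GrowthModelSpec.create("exponential", a=0.1)
    )
    rec = preds.to_record()
    assert rec["max_size_mm3"] == "unbounded"
    assert rec["doubling_time_days"] == pytest.approx(math.log(2) / 0.1)
    assert rec["growth_condition_met"] is True

    shrink = ClinicalPredictions.from_model(
        GrowthModelSpec.create("bertalanffy", a=0.5, b=1.0)
    )
    assert shrink.doubling_time is None
    assert shrink.min_cure_concentration == 0.0
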