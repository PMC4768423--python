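"""Shared fixtures: seeded draws of plausible model parameters."""

from __future__ import annotations

import numpy as np
import pytest

from oncofit.models import GrowthModelSpec


def draw_spec(name: str, rng: np.random.Generator) -> GrowthModelSpec:
    """One random parameter draw in a plausible xenograft range.

    All draws satisfy the growth condition; mendelsohn avoids the b=1
    degeneracy and bertalanffy keeps a > b.
    """

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    if name == "exponential":
        return GrowthModelSpec.create(name, a=logu(0.01, 0.5))
    if name == "mendelsohn":
        b = rng.uniform(0.3, 0.9) if rng.random() < 0.5 else rng.uniform(1.1, 1.8)
        return GrowthModelSpec.create(name, a=logu(0.05, 1.0), b=float(b))
    if name == "logistic":
        return GrowthModelSpec.create(name, a=logu(0.02, 0.5), b=logu(500, 20000))
    if name == "linear":
        return GrowthModelSpec.create(name, a=logu(1, 200), b=logu(50, 5000))
    if name == "surface":
        return GrowthModelSpec.create(name, a=logu(0.1, 50), b=logu(10, 5000))
    if name == "gompertz":
        c = logu(1, 500)
        return GrowthModelSpec.create(
            name, a=logu(0.02, 0.5), b=c * logu(3, 100), c=c
        )
    if name == "bertalanffy":
        b = logu(0.01, 0.5)
        return GrowthModelSpec.create(name, a=b * logu(1.5, 20), b=b)
    raise ValueError(name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
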