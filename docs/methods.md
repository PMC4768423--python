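# Methods

## The models

`oncofit` implements seven classical single-ODE descriptions of solid-tumor
growth, each for the tumor volume V (mm³) over time t (days):

| model       | dV/dt                 | parameters |
|-------------|-----------------------|------------|
| exponential | a V                   | a (/day) |
| mendelsohn  | a V^b                 | a, b (dimensionless exponent) |
| logistic    | a V (1 − V/b)         | a (/day), b (mm³, carrying capacity) |
| linear      | a V / (V + b)         | a (mm³/day late-phase slope), b (mm³) |
| surface     | a V / (V + b)^(1/3)   | a, b (mm³) |
| gompertz    | a V ln(b / (V + c))   | a (/day), b, c (mm³) |
| bertalanffy | a V^(2/3) − b V       | a, b (rates) |

Constant-concentration chemotherapy with kill rate C₀ (per day) subtracts
C₀·V from each right-hand side. All seven treated and untreated systems have
a fixed point at V = 0 plus one other fixed point — a finite stable volume
(the maximum tumor size) or an unbounded attractor. Untreated, exponential,
mendelsohn, linear and surface grow without bound; under any C₀ > 0 only the
exponential model remains unbounded.

## Clinical quantities

For each parameterized model the `analytics` module computes:

- **Maximum tumor size** — the nonzero fixed point: logistic b, gompertz
  b − c, bertalanffy (a/b)³ untreated; under treatment mendelsohn
  (C₀/a)^(1/(b−1)), logistic b(a−C₀)/a, linear a/C₀ − b, surface
  (a/C₀)³ − b, gompertz b·e^(−C₀/a) − c, bertalanffy (a/(b+C₀))³.
  Non-positive values are reported as 0 with an `eradicated` flag. The
  surface entry is the algebraic root of aV/(V+b)^(1/3) = C₀V, which is the
  form consistent with the surface cure condition C₀ = a/b^(1/3) (the fixed
  point vanishes exactly at that kill rate).
- **Doubling time** DT = ln2/λ, where λ is the initial growth rate from
  expanding the right-hand side about V = 0: a (exponential, mendelsohn,
  logistic), a/b (linear), a/b^(1/3) (surface), a·ln(b/c) (gompertz), a − b
  (bertalanffy). For the fractional-power mendelsohn (b ≠ 1) and bertalanffy
  models a strict Taylor expansion at V = 0 is singular; λ there is the
  conventional relative growth rate at unit volume. These entries carry a
  caveat flag in `ClinicalPredictions`.
- **Growth condition** λ > 0, and **minimum cure concentration** C₀ = λ:
  the smallest constant kill rate that makes the tumor-free state
  attracting. For mendelsohn (b < 1) and bertalanffy the V^b / V^(2/3) term
  dominates any linear kill term near V = 0, so the tumor-free state is
  never linearly stabilized; the reported threshold is the unit-volume
  convention and marks where the treated fixed point crosses V = 1 mm³
  rather than a true eradication boundary (hence the caveat flag).

Fixed-point stability is classified numerically by sign-checking the
right-hand side at V*(1 ± 10⁻⁴), which behaves uniformly across the
fractional-power models where symbolic derivatives are singular.

## Trajectories and numerics

`solve_trajectory` integrates with adaptive LSODA at rtol 1e-8 / atol 1e-10
(configurable). Tiny negative excursions are clipped to zero before
fractional-power evaluation to avoid complex values near extinction.
Unbounded growth is terminated cleanly at 10¹² mm³ and reported as a
divergence signal with the last valid time — never a silent NaN or inf.
Closed-form solutions exist and are used for exponential, logistic,
mendelsohn (b ≠ 1; finite-time blow-up for b > 1 reported as divergence)
and bertalanffy (via the substitution u = V^(1/3)). The gompertz equation
with a positive offset c, and the linear/surface equations, have no
elementary solution; callers fall back to the solver. Closed forms and the
solver agree to 1e-6 relative on seeded random parameter draws (tested).

## Fitting and model selection

Fitting minimizes SSR = Σᵢ (xᵢ − mᵢ)² between observed volumes xᵢ and model
predictions mᵢ at the observation times. The initial volume is fixed to the
first observation (configurable), so the free-parameter count K is 1
(exponential), 2 (mendelsohn/logistic/linear/surface/bertalanffy) or 3
(gompertz). Optimization runs in log-parameter space under box bounds:
a ∈ [1e-6, 10]/day (but up to 1e4 for linear and 1e3 for surface, whose `a`
carries volume units), b, c ∈ [1e-6, 1e6] mm³, mendelsohn exponent
b ∈ [0.1, 3]. Each fit multistarts a bounded truncated-Newton (TNC) search
from one data-driven heuristic point plus a seeded Latin-hypercube (default
32 starts), then polishes the best start with a trust-region-reflective
least-squares pass; this combination is deterministic given (data, seed,
n_starts) and recovers noiseless self-generated truths to ~1e-6 relative.
Inside the optimizer loop trajectories are evaluated via closed forms where
available and plain LSODA (`odeint`, rtol 1e-7) otherwise; a diverged or
non-finite trajectory scores a large finite penalty so the optimizer
retreats. The reported SSR is recomputed at tight tolerance.

`residual_mode="relative"` divides residuals by the observations — the
weighted least-squares estimator matched to multiplicative measurement
noise. The default (`"absolute"`) reproduces the unweighted SSR definition
above and is used wherever the comparison experiment is mirrored; the
recovery studies in the test suite use the noise-matched relative mode.

Model selection uses the small-sample-corrected Akaike criterion
AICc = n·ln(SSR/n) + 2(K+1)n/(n−K−2); lowest wins, ties (ΔAICc < 1e-9) go
to fewer parameters. SSR = 0 maps to −∞ so perfect fits rank first;
n − K − 2 ≤ 0 yields an undefined-AICc signal (NaN in `FitResult`).

## Synthetic data

`generate_series` emulates a long subcutaneous-xenograft study: n_points
(default 14) spanning a horizon (default 114 days), interior times jittered
by up to 10% of the nominal spacing, and multiplicative lognormal noise
parameterized mean-1 with coefficient of variation `cv` (default 0.1), so
measurement error scales with tumor size and is unbiased (verified to 2%
over 1000 replicates). Volumes are floored at a minimum reportable value
(default 1e-3 mm³). Each series carries a ground-truth record with the true
parameters and the true clinical predictions.

The default demo truth is gompertz a = 0.015/day, b = 5000 mm³, c = 1 mm³,
v₀ = 100 mm³, chosen so the emulated control curve has slow early growth
(early doubling time ≈ 12 d), an inflection near day 91 (still rising at
day 114) and final volumes in the low thousands of mm³ — the qualitative
profile of a long xenograft control arm. These are illustrative values, not
literature estimates, and are labeled as such in the output metadata.

Per-model truths for the parameter-recovery studies (`RECOVERY_TRUTHS`)
are chosen so every parameter is identifiable from the 14-point design; in
particular the gompertz recovery truth uses c = 150 mm³ with v₀ = 20 mm³,
because the offset c is only informed by observations at volumes comparable
to c. A Fisher-information analysis at this design shows the best
achievable relative standard error for the gompertz c at cv = 0.05 is still
tens of percent for any plausible truth, so recovery accuracy is summarized
as the mean relative error across a model's parameters (median over seeds)
rather than the worst single parameter.

## The comparison experiment

`run_comparison` reproduces the truncation/extrapolation workflow: split a
series into an early half (first ⌈fraction·n⌉ points, default half) and the
held-out remainder; fit every model to the early half; extrapolate each fit
across the full horizon and score the held-out points (prediction SSR);
refit on the full series; compute the clinical quantities for both fits;
and report percent change 100·(full − truncated)/truncated per quantity
(not applicable when either side is unbounded or undefined) plus the
max/min fold spread of each quantity across models (non-finite,
non-positive and non-growing entries excluded, with notes). The report
records separately which model has the lowest fit SSR, the lowest AICc and
the lowest prediction SSR — these can be three different models, and on
noisy synthetic data they frequently are.

Two empirical behaviors of this experiment on the demo truth are worth
knowing. First, on data showing saturation the surface model's SSR-optimal
fit drives b to its lower bound (the pure V^(2/3) limit), where the
tabulated doubling-time formula b^(1/3)·ln2/a degenerates toward zero, so
doubling-time fold spreads can be dominated by this boundary artifact.
Second, adding the second half of the series does not necessarily shrink
the across-model disagreement in doubling time: the mendelsohn exponent
drops as saturation appears and its unit-volume rate λ = a rises, widening
the spread. Conclusions drawn from a single dataset about the effect of
more data need not generalize.

## Problem sizes and defaults used in checks

The test suite and `scripts/acceptance.py` use 20 random parameter draws
per model for structural/root-finding checks, 10 noise seeds for the
recovery and truncation experiments, and 8 multistarts per fit (the
heuristic start plus Latin-hypercube; on these well-conditioned synthetic
problems additional starts do not change the optima, as spot-checked with
64 starts).

## Limitations

- Constant drug concentration only; no pharmacokinetics, scheduling,
  resistance or combination therapy.
- No animal-to-animal hierarchy in the generator, no digitization error
  model, and no claim that any synthetic series reproduces a specific
  published dataset.
- Doubling times and cure thresholds for the fractional-power models follow
  the tabulated unit-volume conventions; they are flagged, not reinterpreted.
- Passing recovery tests on synthetic lognormal noise does not guarantee
  comparable accuracy on real caliper data, whose error structure includes
  serial correlation and handling effects the generator does not emulate.
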