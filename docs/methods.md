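# Methods

## The model

A day is a composition of time: sleep, sedentary behaviour (SB), light
physical activity (LIPA) and moderate-to-vigorous physical activity
(MVPA) jointly fill 1440 minutes (or the waking day, typically 960
minutes, when sleep is not measured).  Only relative information is
meaningful in such data, so the package works throughout in isometric
log-ratio (ilr) balance coordinates with the nested contrast system

    z1 = sqrt(3/4) ln( Sleep / (MVPA · LIPA · SB)^{1/3} )
    z2 = sqrt(2/3) ln( MVPA  / (LIPA · SB)^{1/2} )
    z3 = sqrt(1/2) ln( LIPA  / SB )

chosen so that sleep enters through a single coordinate.  This makes the
system subcompositionally coherent: z2 and z3 are identical whether
computed from the 4-part day or from the waking 3-part subcomposition,
which is what lets studies that never measure sleep share the waking
coordinates with studies that do.  The contrast matrix is orthonormal
(`B Bᵀ = I`), hard-coded to this basis; other ilr bases give equivalent
fits and are deliberately out of scope.

Mortality is modelled with a proportional-hazards regression whose
linear predictor combines the ilr coordinates with ordinary covariates:

    ln h(t; z, v) / h0(t) = γᵀ z + βᵀ v

`exp(γ_j)` is the hazard ratio for a one-unit increase of balance `j`
holding the others fixed.  The hazard ratio between any two compositions
follows from linearity,

    HR = exp( γᵀ (z(comp) − z(ref)) ),

and is the single identity behind every downstream display: unit-HR
tables, dose–response reallocation curves, isotime heat maps over the
(MVPA, SB) plane, and minutes-of-substitution solving.

## Federated pooling

Studies share only `(γ̂, Σ̂)`.  Estimates are combined with a
multivariate random-effects model `γ̂_i ~ N(μ, S_i + Ψ)`; the pooled mean
is the GLS combination with weights `(S_i + Ψ)^{-1}`.  Ψ is estimated by
REML over a log-Cholesky parameterisation (direct Nelder–Mead
maximisation with a PSD projection of the result); a per-coordinate
DerSimonian–Laird method-of-moments estimator (`method="mm"`, diagonal
Ψ) and a fixed-effect mode (`Ψ = 0`) are available.  In one dimension
`method="mm"` is exactly DerSimonian–Laird, which is the closed form the
tests check against.

Waking-only studies are aligned to the 3-coordinate system by setting
their sleep coefficient to zero with an arbitrarily large variance
(default `1e6` on the coefficient scale; any value ≥ `1e4` gives
indistinguishable pooled results, which a test asserts).  Their weight
on z1 is then ~`1e-6` relative, so they inform z2/z3 without touching
the sleep balance.

Heterogeneity is summarised per coordinate with fixed-effect-weighted
Cochran Q, its chi-square(k−1) p-value and `I² = max(0, (Q−df)/Q)·100`;
coordinates that are masked in a study are excluded from that
coordinate's Q.  Leave-one-out pooling and device-placement strata
(wrist/hip) cover the sensitivity analyses.

## Per-study fitting choices

* Partial-likelihood maximisation is delegated to lifelines'
  `CoxPHFitter` with the Efron tie approximation (the accepted default,
  and it matters for coarsely recorded follow-up).  The coefficient
  covariance is the inverse observed information restricted to the ilr
  block.
* Reverse causation is limited by a landmark filter that removes deaths
  in the first 2 years of follow-up.  Subjects *censored* early are
  retained (the filter targets deaths, not all early exits); a
  `drop_all_early` flag provides the stricter variant.  Follow-up clocks
  are not reset at the landmark.
* Proportional hazards: the per-coefficient Grambsch–Therneau
  scaled-Schoenfeld score tests come from lifelines; the global
  statistic `T = uᵀ (d V) u / Σ(g_k − ḡ)²` with
  `u = Σ (g_k − ḡ) s_k` (Schoenfeld residuals `s_k`, Kaplan–Meier
  transformed event times `g`, `d` events, coefficient covariance `V`)
  is computed in-package because lifelines exposes no global test.  Its
  type-I error is verified by simulation (rejection rate within
  [0.03, 0.08] at α = 0.05 over 200 proportional-hazards cohorts).

## Rounded zeros

A recorded zero (almost always MVPA) is a censored small value below the
device's detection limit, not a true absence.  Zeros are imputed with an
EM algorithm on additive log-ratio coordinates: initialise by
multiplicative simple replacement at 0.65 × limit, then iterate an
M-step (normal fit to the completed log-ratio data) and an E-step that
replaces each censored coordinate by its conditional expectation
truncated above at the censoring threshold; convergence when imputed
log-ratios move < 1e-4, capped at 50 iterations.  Default detection
limit is 1 min/day per behaviour (1-minute epochs), overridable per
study.  Guarantees tested: zero-free rows pass through unchanged up to
closure, imputed raw values are strictly inside (0, limit), observed
parts keep their mutual ratios exactly, and rows are re-closed to their
original totals (imputation precedes re-closure).  A detection limit
exceeding the smallest observed non-zero value is logically inconsistent
with the data and is warned about.

## Reference compositions and effect displays

The reference composition is data-driven: a bivariate normal is fitted
to the observed (z2, z3) cloud and the reference is the inverse-ilr of
`μ + r Σ^{1/2} u` with `r² = χ²₂(coverage)` (default coverage 0.75), i.e.
a point on the 75% Mahalanobis contour in a configurable direction
(default `(-1, -1)/√2`, targeting low MVPA and a low LIPA:SB balance —
the natural "poorly active but data-supported" corner; the direction is
exposed because the choice is genuinely open).

Dose–response curves reallocate time into one behaviour while the
remaining behaviours keep the reference's mutual ratios; a two-behaviour
mode pins SB and lets LIPA absorb the remainder.  Heat maps evaluate the
waking composition (MVPA=m, SB=s, LIPA=960−m−s) on default grids MVPA
1–120 min (step 1) × SB 420–900 min (step 5); cells with non-positive
implied LIPA are masked infeasible.  Substitution solving finds the δ
minutes moved out of SB (into MVPA with LIPA fixed, or into LIPA with
MVPA fixed) reaching a target HR by Brent root search on a bracket
δ ∈ (0, SB_ref − 1); results are reported to the nearest minute.

Confidence intervals are Wald intervals on the log-HR with variance
`Δzᵀ V_γ Δz`, treating compositions as fixed — exact, not a delta-method
approximation, because the log-HR is linear in the coefficients.
Substitution CIs solve the same root-finding problem on the upper/lower
Wald HR-bound curves, which is what produces the strongly asymmetric
minute intervals; a curve that never crosses the target yields a
no-solution result carrying the attained infimum.

A note on printed-precision reproduction: with the published hip
coefficients rounded to three decimals, the third MVPA-for-SB reference
(MVPA=30, LIPA=330, SB=600) has its exact root at 51.44 min, which
rounds to 51 rather than the published 52 — the published table was
evidently computed with unrounded pooled coefficients.  The same cause
makes the third published equal-risk heat-map point evaluate to ≈0.75
rather than 0.70; both are documented rather than adjusted.

## Synthetic cohorts

The generator draws compositions logistic-normally — normal in ilr space
(the same distributional family the reference-selection step fits to
real data), inverse-transformed and closed to the configured total.
Defaults emulate the motivating cohorts: a hip-like waking centre of
(MVPA, LIPA, SB) = (8.2, 355.5, 596.3) min (4-part default centre
(Sleep, MVPA, LIPA, SB) = (437.3, 61.8, 122.6, 818.3) min), ilr
covariance 0.25² I, one Bernoulli(0.5) and one standard-normal
covariate, true γ on the scale of the published coefficients, an
exponential (optionally Weibull) baseline with administrative censoring
at an 8-year horizon minus a uniform 2-year entry stagger, and a default
event fraction near 3% (the pooled mortality rate of the motivating
studies; recovery experiments use a higher rate — 0.0125/year, ≈30%
events — so coverage assessment is informative at n=2000).  MVPA below
the detection limit can be recorded as zero with a configured
probability to exercise the imputation path.

Per-subject randomness comes from child streams of one root seed
(`SeedSequence.spawn`), so enlarging `n` never reshuffles earlier
subjects and every artefact is byte-reproducible from config + seed.

What the generator does *not* emulate: real accelerometer measurement
error and wrist/hip misclassification, covariate confounding structure,
non-proportional hazards, informative censoring, and between-study
covariate harmonisation.  Passing recovery tests therefore demonstrate
that the estimation machinery is correct under the model's own
assumptions, not that those assumptions hold in any particular cohort.

## Problem sizes and numerical settings

Validation experiments use 200 replicates of n=2000 cohorts for Cox
recovery (bias and CI coverage), 200 replicates of n=500 for PH-test
calibration, and k=20 simulated studies over 40 replicates for pooling
recovery — sizes at which Monte-Carlo error is small relative to the
asserted tolerances while the whole suite stays fast.  Root solving uses
`brentq` with a tolerance far below one minute so round trips through
the HR identity reproduce targets to ~1e-6.  Compositions deviating from
their stated total by more than 1e-6 relative are re-closed with a
warning rather than rejected.  JSON serialisation uses Python's
shortest-repr floats, which round-trip bit-exactly.

## Known limitations

* The REML Ψ estimate at k as small as published meta-analyses (2–4
  studies per stratum) is noisy; the mm/fixed fallbacks exist for that
  reason.
* The lrEM implementation requires at least one fully observed part to
  anchor the alr reference.
* No left truncation, time-varying coefficients, competing risks or
  frailty; cause-specific mortality is out of scope.
* Published pooled cohort-level coefficients and the overall I² cannot
  be recomputed here: they require access-restricted subject data.
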