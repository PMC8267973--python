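# Methods

## Model

Carotid intima-media thickness (IMT) for a patient group is modelled as a
logistic function of chronological age t (years, t = 0 at birth):

    dx/dt = a x (1 - x/c),   x(0) = x0
    x(t)  = c x0 e^{a t} / (c + x0 (e^{a t} - 1))

with three parameters per group:

| parameter | units  | meaning                                             |
|-----------|--------|-----------------------------------------------------|
| x0        | mm     | model IMT at age 0 (an abstraction, not a neonatal measurement) |
| c         | mm     | carrying capacity — the terminal IMT the trajectory converges to |
| a         | 1/year | growth-rate coefficient                             |

Validity requires 0 < x0 < c and a > 0 (the growth regime); the
`LogisticParams` constructor rejects anything else.  Three analytic
statistics follow: the inflection age t* = ln((c − x0)/x0)/a, the IMT there
x(t*) = c/2, and the maximum slope a·c/4.  When x0 ≥ c/2 the inflection
falls at or before birth; this is mathematically legitimate and is reported
with a `pre_observation` flag rather than rejected, since a fitted cohort
can in principle start past its steepest point.

The treatment-timing layer rests on one clinical argument: if statins
subtract a roughly fixed amount from the growth rate, the subtraction is
worth most where growth is fastest, so the recommended start age is the
inflection age rounded to the nearest integer year (halves away from zero,
the convention used for reporting ages like "≈38").  Group contrasts use
differences of *rounded* inflection ages — so the aggregate-vs-non-medicated
gap is 38 − 21 = 17 years even though the unrounded difference is 17.5 —
and ratios of peak slopes.

## Numerical evaluation

The closed form is evaluated as c·expit(a·t − ln((c − x0)/x0)) via
`scipy.special.expit`, which is exactly equivalent algebraically and cannot
overflow for any real age (the naive form overflows once a·t exceeds ~700).
Inside the optimiser, where trial points may violate x0 < c, the equivalent
form c·x0/(x0 + (c − x0)e^{−a t}) is used; its denominator stays positive
for all t ≥ 0 and any positive (x0, c).

The secant (x(t2) − x(t1))/(t2 − t1) is used for average slopes over an age
window.  For the legacy dialysis curve on [58, 67] it gives 0.0266 mm/y;
alternative definitions (midpoint tangent 0.0267, endpoint average 0.0262)
were considered and the secant adopted as the plain meaning of "the slope
between two ages".

## Calibration

`fit_logistic` minimises the sum of squared residuals over a bounded box
with multi-start trust-region least squares (`scipy.optimize.least_squares`,
method `trf`):

- bounds: x0 ∈ [0.01, 0.9], c ∈ [0.3, 3.0], a ∈ [0.001, 0.5] — wide margins
  around every group fit this package ships as reference values;
- 20 starts by default, drawn uniformly in the box from a seeded
  `numpy.random.Generator`; the best converged start by SSE wins, exact ties
  break to the lexicographically smallest (x0, c, a);
- observations are put in a canonical (age, IMT) order before any sum, so
  every statistic is invariant to row order down to the last bit;
- starts converging to x0 ≥ c are discarded; if no start survives, the fit
  raises with diagnostics rather than returning a boundary artefact.

Two auxiliary modes exist because the identification method behind
round-valued fits like (0.3, 1.2) is not documented anywhere: a coarse
exhaustive lattice (`fit_logistic_grid`) and a fix-some-parameters mode
(`FitConfig.fix`), e.g. pinning (x0, c) and optimising a alone.

Goodness of fit reports SSE, RMSE and R² = 1 − SSE/SST (SST about the
cohort IMT mean).  R² can be negative for nonlinear fits and is reported
as-is.  Two RMSE denominator conventions are in circulation for these
tables — sqrt(SSE/(n−1)) and sqrt(SSE/n) — and both reproduce their
respective published values to four decimals, so the convention is an
explicit `rmse_dialect` field defaulting to `n_minus_1`.  A cohort with
identical IMT everywhere but nonzero SSE yields R² = −inf with a warning.

## Synthetic cohorts

`generate_cohort` emulates the structure of the clinical samples: one age
per patient drawn uniformly on the cohort age range (19–74 y for the
current-study groups, 53–78 y for the legacy dialysis sample); for
bilateral cohorts two artery measurements (L/R) at that shared age; IMT =
x(age) + ε with ε ~ N(0, noise_sd) independent per side, truncated below at
0.05 mm.  The four presets use the published parameter triples as ground
truth, the published group sizes (62/18/44/11 observations), and noise_sd
equal to each fit's published RMSE — the only dispersion information
available.

What the generator does **not** emulate: the real (unknown, likely
non-uniform) age distribution; within-patient L/R correlation beyond the
shared true curve; any clinical covariates; measurement error that varies
with age or operator.  Passing recovery tests therefore show the estimator
works under idealised Gaussian sampling at the study's noise level, not
that the clinical fits themselves are unbiased.

## Identifiability at the study noise level

The study noise level is severe: 0.16 mm of noise on a signal that spans
only ~0.54 mm across ages 19–74.  A local information analysis at the
aggregate-group truth (Jacobian of the curve at 620 uniform ages,
covariance σ²(JᵀJ)⁻¹) gives asymptotic relative standard errors of roughly
11% (x0), 19% (c) and 26% (a), i.e. best-case median absolute errors near
8%, 13% and 17%.  Monte-Carlo refits match: over 50 seeded replicates at
n = 620 the median relative errors are about 9.5% (x0), 13% (c) and 19.5%
(a), with c occasionally running to its prior bound (which also induces a
positive bias in c at this noise level; at noise 0.05 mm all biases fall
below 2%).  The fitted *curve*, by contrast, is well determined: refits
track the generating trajectory within ~0.03 mm across the observed ages
even when (c, a) trade off along their ridge.  The narrow 53–78 y window of
the legacy sample degrades identifiability much further — replicate fits of
that design scatter widely in c — which is the structural reason fits from
such designs carry mixed goodness-of-fit statistics.

## Problem sizes and determinism

All headline quantities are analytic functions of the reference parameter
triples and run in microseconds.  Simulation studies use 50 replicates at
620 observations for recovery, a 50³ lattice for the brute-force
cross-check on cohorts of ≤ 12 points, and 5000-patient cohorts for
noise-calibration checks; the full suite runs in well under a minute.  All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
identical seeds give bit-identical cohorts and fits.

## Known limitations

- Observations are treated as independent; bilateral measurements from one
  patient are not clustered, and no mixed-effects structure is offered.
- Point estimates only: no confidence intervals on parameters (the weak
  identifiability above is exactly why interval estimates would be wide).
- The model describes thickness, not plaque morphology or composition.
- Recommendations at ages outside the observed span are extrapolations of
  a three-parameter curve and are flagged as such.
- The medicated-vs-aggregate slope ordering (medicated below) holds through
  the observed ages but reverses near age 71, because the medicated curve's
  smaller a makes its slope decay more slowly; statements about "remaining
  below" are restricted to the observed span.
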