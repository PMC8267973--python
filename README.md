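# imtlogistic

Logistic growth-curve modelling of carotid intima-media thickness (IMT),
with a treatment-timing layer that turns a fitted curve into a recommended
statin-start age.

Atherosclerotic plaque thickening, measured by ultrasound as IMT (mm), is
modelled as an S-shaped function of patient age: slow in youth, fastest in
mid-life, flattening toward a terminal thickness.  The package is for
biostatisticians and modellers who want to calibrate that curve to cohort
data, reason about when growth is fastest, and stress-test the whole
pipeline on synthetic cohorts with realistic structure and noise.

## Model

IMT at age t (years) follows the logistic law

    dx/dt = a x (1 − x/c),  x(0) = x0
    x(t) = c x0 e^{at} / (c + x0 (e^{at} − 1))

with x0 the model IMT at birth (mm), c the carrying capacity (terminal IMT,
mm) and a the growth-rate coefficient (1/year).  The curve is steepest at
the inflection age

    t* = ln((c − x0)/x0) / a,   where x(t*) = c/2 and dx/dt = a·c/4.

If statin treatment subtracts a roughly constant amount from the growth
rate, it buys the most where growth is fastest — so the recommended start
age is t* rounded to the nearest year.

The package ships reference parameter triples for four male cohorts
(severely sick aggregate, its non-medicated and statin-medicated subsets,
and a legacy dialysis sample), a calibrator (bounded multi-start nonlinear
least squares, plus a coarse-grid mode), a synthetic-cohort generator that
reproduces each group's size, age window, bilateral L/R structure and noise
level, and a CLI.

## Worked example

```python
from imtlogistic import (REFERENCE_CURVES, inflection, mean_slope,
                         presets, generate_cohort, fit_logistic, FitConfig)

agg = REFERENCE_CURVES["aggregate"]          # x0=0.3, c=1.2, a=0.02875
summ = inflection(agg)
print(summ.rounded_age, summ.x_star, summ.max_slope)
# 38 0.6 0.008625  -> steepest growth at ~38 y, IMT 0.6 mm, 0.008625 mm/y

nonmed = REFERENCE_CURVES["non_medicated"]
print(summ.rounded_age - inflection(nonmed).rounded_age)
# 17  -> the non-medicated subset inflects 17 years earlier

legacy = REFERENCE_CURVES["dialysis_legacy"]
print(round(mean_slope(legacy, 58, 67), 4))
# 0.0266 -> the legacy dialysis curve's average slope over 58-67 y,
#           more than 3x the aggregate's peak slope

cohort = generate_cohort(presets(seed=0)["aggregate"])   # 62 noisy points
fit = fit_logistic(cohort, FitConfig(seed=0))
print(fit.n, round(fit.rmse, 4))
# 62 0.1679 -> refit RMSE close to the 0.16 mm generating noise
```

The same numbers mean: an aggregate severely-sick cohort is growing plaque
fastest around age 38, which is the candidate window for starting statins;
the non-medicated subgroup's curve peaks near 21; and the legacy dialysis
cohort shows much faster (accelerated) thickening in its observed 53–78 y
window.

The end-to-end analyses live under `analysis/` as numbered scripts
(`01_reference_curves.py` … `04_timing_analysis.py`); each prints what it
found and writes its tables under `results/`.  The CLI offers the same
pipeline from a shell:

```
imtlogistic simulate --preset aggregate --seed 0 --out cohort.csv
imtlogistic fit cohort.csv --out fit.json
imtlogistic recommend fit.json
```

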