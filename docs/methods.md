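# Methods

## Problem and estimands

The package quantifies carbohydrate quality in adolescent 24 h-recall data
at two resolutions — the whole day (DGI, DGL) and the eating occasion
(AvGI, AvGL, the within-day "peak" summaries) — and estimates the adjusted
linear association between each metric (z-standardized) and three
glycemic-control markers (fasting insulin, HOMA-IR, HbA1c), separately for
normal-weight (NW) and overweight/obese (OW) students, under a stratified
two-stage school sample.

## Metric definitions and conventions

Glycemic carbohydrate per food is total carbohydrate − fiber (g per 100 g),
clamped at 0 with a logged warning when a composition table reports fiber in
excess of carbohydrate (a real artifact of compiled tables; clamping keeps
weighted-mean denominators non-negative).

GI resolution order: zero-GI class rules first (diet/light carbonated
beverages, high-alcohol distilled spirits, meat/offal/sausages — these are
definitional overrides, so they beat a conflicting table entry, with the
conflict logged), then a direct or literature table entry, then a one-step
similar-food-in-composition substitution. Chained similar-food references
are a validation error (prevents cycles); an exhausted chain is a hard
error, never an imputation. GIs are validated to [0, 150]: glucose-reference
foods can exceed 100, values above 150 are table defects.

Per occasion, GI is the carbohydrate-weighted mean of food GIs (undefined
when the occasion has no glycemic carbohydrate) and GL is Σ carb×GI/100.
AvGI averages occasion GIs over carbohydrate-bearing occasions only (GI is
undefined elsewhere); AvGL averages occasion GLs over **all** reported
occasions by default, which preserves AvGL × occasion count = DGL and makes
the DGL/AvGL ratio interpretable as the mean number of eating occasions.
Averaging occasions with weights would collapse AvGI into DGI and defeat
the peak/whole-day contrast, so the occasion means are unweighted. The AvGL
divisor is switchable (`avgl_occasions="carb_only"`) because survey
practice varies. Aggregation order is fixed (sort by student, occasion
order, occasion id, food id) so outputs are bit-reproducible.

A day with zero glycemic carbohydrate has DGI/AvGI missing and DGL = 0; such
students drop out of GI models by listwise deletion.

Occasion-GI distribution summaries use linear-interpolation quartiles and
Tukey whiskers (most extreme observations within 1.5 IQR of the quartiles);
a group × occasion-order cell with no data is absent, not zero.

## Clinical variables

HOMA-IR uses the Matthews mg/dL convention glucose × insulin / 405; the
pediatric literature this kind of study draws on uses the same form. Inputs
outside plausibility windows (glucose 30–400 mg/dL, insulin (0, 300] mU/L)
make the marker missing with a logged reason — mirroring how implausible
assays are accounted as missing — rather than raising. Weight status:
BMI z < 1 normal, ≥ 1 overweight, ≥ 2 obese, analyzed as NW vs OW
(overweight ∪ obese). Physical activity: 0 min/week inactive, (0, 300)
insufficiently active, [300, 2100] active, > 2100 discarded as low-quality
self-report (boundary 300 is active, 2100 is retained — both read literally
from the category definitions). Self-reported diabetics are excluded before
analysis; all other missingness is handled listwise per model, so each
marker model keeps its maximal sample. BMI z-scores are accepted as input;
computing them from anthropometry against a growth reference is out of
scope.

## Survey estimation

Point estimates are weighted least squares. Variance is first-stage
with-replacement Taylor linearization: score contributions w·x·e are summed
to PSU (school) totals; within stratum h with n_h PSUs the contribution is
n_h/(n_h−1) times the centered outer-product sum; the sandwich uses
(X'WX)⁻¹. No finite-population correction (school sampling fractions
unknown). Inference is t with df = #PSUs − #strata. The same engine yields
descriptive means and 95% CIs, so Table-style descriptives and regressions
share one variance estimator. Robust SEs are invariant to rescaling all
weights by a constant, and with equal weights/one stratum/unit PSUs the
estimates collapse to OLS — both asserted in tests against statsmodels as
an independent oracle.

Each of the 24 grid models (3 markers × 4 metrics × 2 weight strata)
re-standardizes its metric within the fitted subset with weighted moments
(population SD convention, divide by Σw); the weighted mean-0/SD-1 property
is asserted on every fit. Whole-sample standardization is available by flag
(`standardization_scope="whole_sample"`) because "standardized values" in
stratified reports is ambiguous; within-stratum is the default so the
statement holds inside each fitted model. HbA1c is modelled on the % scale
as printed. No multiple-testing adjustment (per-model p-values are the
convention being emulated). Single-PSU strata raise by default; a merge
strategy (fold into the adjacent stratum in sorted label order) is opt-in.
Rank-deficient designs raise naming the collinear columns via pivoted QR.

## Energy accounting

Energy = 4·carbohydrate + 4·protein + 9·lipid kcal/g, computed per food and
aggregated per student; percent of energy is computed from group means, so
the three shares sum to 100 before integer rounding. The food-table format
carries optional `protein_g`/`lipid_g` columns (default 0) for this purpose.
Group summaries of energy intake published for this population are
internally consistent with these factors, which is checked in the
acceptance tests against the shipped calibration targets.

## Synthetic cohort

The generator emulates the study conditions of a national school-based
adolescent survey; its defaults are those conditions, calibrated once
against the published group means shipped in
`data/calibration_targets.csv`:

- design: 4 strata × 10 schools × 50 students (n = 2000); lognormal(0, 0.3)
  sampling weights; 60% girls; age U(12, 17); maturation stage 1–5 coupled
  to age; OW prevalence 25% (≈ 1/3 obese within OW); 3.3% self-reported
  diabetes; PA with a sex-specific zero mass and lognormal minutes, a few
  percent exceeding the 2100 min/week quality cap.
- diet: 3–6 occasions/day with probabilities (0.15, 0.40, 0.30, 0.15) for
  3/4/5/6 — mean 4.45, matching the DGL/AvGL ratio of the targets; meal
  schedule breakfast(–snack)–lunch(–snack)–dinner(–snack). Foods are drawn
  from a ~50-item catalog (low-GI bean/rice staples through high-GI
  sweets/drinks plus zero-GI meats, diet soda, spirit) with a Gaussian
  GI-kernel whose center shifts by `lunch_gi_shift` (−8, the rice-and-beans
  lunch regime) and `snack_gi_shift` (+8, sweets/sodas between meals); with
  both shifts 0 every occasion type draws identically, giving a clean null
  for patterning tests. Daily glycemic-carbohydrate targets: 280 g for NW
  girls (≈ DGL 165 at DGI 59), ×1.18 for boys, ×0.855 for OW students (the
  published OW/NW intake ratio), lognormal day-to-day spread CV 0.30.
  A small share of snacks is diet-soda-only, exercising zero-carbohydrate
  occasions.
- markers: generated conditional on the *computed* metrics, so estimation
  targets are unambiguous: marker = baseline(sex, OW) + small age/
  maturation/PA terms + Σ β·z(metric within weight stratum, weighted) +
  school effect + residual. Default planted effects: insulin–AvGL β = 0.12
  in NW, insulin–AvGI β = 0.23 in OW, HbA1c–AvGL β = 0.006 in NW. Baselines
  reproduce the target group means (insulin 8.71/13.20 girls NW/OW,
  7.10/12.04 boys; glucose 84–88; HbA1c 5.33–5.42). Residual SDs: insulin
  3.0 mU/L, glucose 6.0 mg/dL, HbA1c 0.30%; school-level SDs 0.4/0.8/0.05.
  HOMA-IR is *derived* from generated glucose and insulin through the
  clinical module, never simulated. One recall day per student; an optional
  flag emits a 10%-subsample second day (no usual-intake correction is
  implemented or intended).

What the generator does **not** emulate: real food-frequency structure and
mixed-dish decomposition, skewed insulin distributions (markers are
conditionally Gaussian with mild clipping), informative nonresponse,
within-person day-to-day correlation, and weight construction/calibration.
Passing tests therefore demonstrate the correctness of the metric algebra
and the calibration of the design-based estimator under a correctly
specified linear model — not robustness to those real-data features.

## Numerical and testing choices

Problem sizes were chosen to keep the full suite fast while leaving
estimator checks well-powered: metric identities on 1000 randomized days at
1e-9 relative tolerance backed by an explicit-loop oracle; coverage/bias of
the planted insulin–AvGL effect over 200 replicate n=2000 cohorts (95% CI
coverage asserted in [0.92, 0.98], |bias| < 20% of β); design-collapse
agreement with OLS at 1e-8. statsmodels supplies the independent
cluster-robust covariance oracle (the with-replacement Taylor covariance
equals the uncorrected cluster sandwich times G/(G−1) when an intercept is
present); the survey estimator itself is implemented here.

## Known limitations

Similar-food GI substitution is depth-1 by design; composite recipes are
treated as single recall lines (no decomposition rule is published for the
emulated instrument). The lonely-PSU merge strategy is label-order-based,
not geography-aware. Sampling-weight construction, assay methodology and
blood-pressure outcomes are out of scope.
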