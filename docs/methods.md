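# Methods

This note documents the models implemented in `cdwheat`, the synthetic
data they are exercised on, and the numerical and design choices that
were genuinely open.

## Transfer models

Grain Cd is modelled as a log-linear function of soil variables,

    log10(Cd_wheat) = β0 + Σ βj · zj ,

where each `zj` is either a soil property used untransformed (pH, CEC in
cmol/kg) or a log10-transformed Cd pool.  Three pools are supported:
total soil Cd (mg/kg), 0.01 M CaCl₂-extractable Cd (mg/kg), and
multi-surface-speciation-model dissolved Cd (mg/L at a 1:10
solid–liquid ratio).  The speciation calculation itself is out of scope:
`cd_msm` is an input column (or a generator proxy), never recomputed
thermodynamically.  Because the three pools are strongly mutually
correlated, the fitting layer refuses feature sets containing more than
one of them.

All logarithms in the package are base 10; the published coefficient
sets are only mutually consistent (equation, fit quality, inverted
thresholds) on that base.

Fitting is ordinary least squares via statsmodels on the log10 response,
so the exported standard errors, t-based p-values and R² are the
textbook OLS quantities.  R² is reported as 1 − SSE/SST on the evaluated
set (it may be negative for a bad model on a test set; it is not
clamped).  RMSE and MAE are computed on log10(mg/kg) residuals: on the
original scale they would be dominated by the most contaminated samples,
and the magnitudes quoted for models of this family (RMSE ≈ 0.2–0.33 for
a response averaging ≈ 0.3 mg/kg at R² ≈ 0.7) are only coherent as
log-scale errors.

The quadratic bioconcentration-factor model, BCF(pH) = a·pH² + b·pH + c
with shipped coefficients (0.014, −0.236, 1.113), captures the
empirically observed flattening of the pH effect above pH ≈ 7; grain Cd
is then BCF(pH)·Cd_soil.

A design note on sample-size guards: a model with p features is fit
whenever at least p+1 complete records are available — the smallest
identifiable design.  With exactly p+1 records the fit interpolates
(R² = 1) and standard errors are undefined; they are reported as NaN
rather than refused.

## Threshold back-calculation

With the grain limit L (default 0.1 mg/kg) fixed, a log-linear model is
solved in closed form for its Cd pool:

    threshold = 10^[(log10 L − β0 − Σ_{j≠cd} βj zj) / β_cd] ,

and the BCF model gives L / BCF(pH).  Inversion is exact: the package
verifies predict(invert(L)) = L to 1e-9 relative and agreement with a
bisection oracle on [1e-4, 100] to 1e-6 in its test suite.

Thresholds are continuous in pH.  For comparison with the stepwise
standards they are tabulated at one representative pH per band; the
default convention is the band lower boundary (5.5, 6.5, 7.5), with the
open-ended acid band represented at pH 4.0.  The convention is a
parameter of `threshold_table` and is recorded in the table's metadata,
because no single convention is canonical.  When a model references CEC,
the tabulated curve uses a fixed CEC default, conventionally the mean
CEC of the dataset under study.

Protection accuracy classifies each record twice — soil Cd against the
rule's threshold at the record's pH, grain Cd against the limit — and
summarizes TP/FN/FP/TN with Acc% = (TP+TN)/n × 100.  Two behaviours are
distinguished for CEC-bearing curves: with a fixed CEC default the rule
is the practical, tabulated one; with no default the curve is inverted
at each record's own CEC, which makes classification exactly
self-consistent on data generated from the same equation (Acc = 100% in
the noise-free limit, a property the tests assert).  Strict inequality
(`>`) defines exceedance on both axes, so boundary records are treated
identically on the soil and grain side.

The two encoded step standards are GB 15618–2018
(0.30/0.30/0.30/0.60 mg/kg across the four pH bands) and GB/T 41685–2022
(0.20/0.23/0.30/0.36 mg/kg); boundary pH values belong to the lower
band, matching the bands' ≤ notation.

## Data cleaning

Cleaning removes, in one pass: records missing any required field, then
records whose raw BCF lies outside mean ± 3 sample SD of the BCF of all
records surviving the missing-value filter.  The screen uses raw (not
log) BCF and does not recompute the SD after removals.  The applied
bounds are frozen into the cleaned dataset's provenance and re-applied
if an already-cleaned dataset is cleaned again, making the operation
idempotent rather than an iterated trim — an iterated 3-SD trim on a
right-skewed BCF distribution would keep shaving the tail indefinitely,
which is not the intent of a one-shot outlier screen.

## Synthetic data generator

The generator emulates the 311-record field/literature survey the model
suite was developed on.  What it reproduces:

- **Marginals.** Six soil properties are independent truncated normals
  bounded by the published ranges; the pH location is the published mean
  5.65.  Published SDs do not exist, so scales are set so the range ends
  sit near ±2.5 SD (pH 0.92; CEC 5.33; clay 11.05; SOM 12.6; DCB-Fe
  3.98; ox-Fe 2.01 — units as the properties).  Range-midpoint locations
  are used where no mean is published, except CEC (below).  Total soil
  Cd is a truncated log-normal on [0.068, 13.5] mg/kg with log10-SD 0.45
  and log10-mean −0.094, solved numerically so the arithmetic mean is
  1.329 mg/kg.
- **Pathway structure.** The bioavailable pools follow empirical
  log-linear partition proxies, log10(pool) = α0 + α1 log10(Cd_soil) +
  α2 pH + α3 CEC + ε, with signs (+, −, −): more total Cd, lower pH and
  lower CEC all raise dissolved Cd.  Defaults (CaCl₂: 0.388, 1.0, −0.20,
  −0.010, noise SD 0.25; dissolved: −0.44, 1.0, −0.25, −0.010, noise SD
  0.30) put the mean CaCl₂-extractable Cd near the reported 0.230 mg/kg
  and keep the physical clip `cd_cacl2 ≤ cd_total` active in well under
  1% of draws.  These are proxies, not speciation chemistry.
- **Response.** Grain Cd follows the shipped M2 equation plus
  Normal(0, 0.25) log10 noise.  The noise default makes a refitted
  M2-type model attain R² ≈ 0.65–0.8, bracketing the fit quality such
  models reach on real survey data.
- **Calibration target.** The CEC location (10.5 cmol/kg, below the
  range midpoint) is the one free location parameter and was tuned by
  simulation so the generated mean BCF centres on the reported 0.26;
  default datasets of 311 records have mean BCF within 0.23–0.29 across
  seeds.

What it does **not** reproduce, and what passing tests therefore do not
show about real data: cross-correlations among soil properties (no
covariance matrix is published; properties are sampled independently),
spatial or provenance structure (literature vs. survey records),
measurement error in soil Cd, wheat-variety effects, and any
dataset-specific performance number.  Published dataset-bound values —
per-model R²/RMSE/MAE, individual Pearson coefficients, path-model
effects, ERT feature-importance percentages, and the standards' accuracy
percentages — depend on the undeposited survey and are deliberately not
reproduction targets; the package reproduces the *procedures* and
demonstrates their properties (sign structure, self-consistency, exact
threshold algebra) on synthetic data.

Outlier planting (for cleaning tests) raises the grain Cd of k records
so their BCF lands at ten times the 3-SD bound of the clean BCF
distribution — far enough out that they remain outliers even after they
inflate the screen's own SD.

## Machine-learning benchmark

The harness compares ridge regression, a decision tree, RBF support
vector regression, k-nearest neighbours, random forest, extremely
randomized trees, gradient-boosted trees and XGBoost on log10 grain Cd,
with features total Cd (log10) plus the six soil properties.  Protocol
per repeat: a seeded 4:1 train/test split; hyperparameter selection by
10-fold cross-validation inside the training set over a small, fully
documented grid (trees ∈ {100}; depth ∈ {None, 10}; k ∈ {3, 5, 7};
ridge α ∈ {0.1, 1, 10}; SVR C ∈ {1, 10}; boosted models at 100 trees,
library-default depth), plus a recorded 9:1 pre-train/validation score;
final metrics on the untouched test split.  Tree count is fixed at 100
because ensemble performance plateaus there on data of this size.
Feature importances are impurity-based shares normalized to sum to 1 and
averaged across repeats.  Test-set records never enter cross-validation
or pre-training within their repeat, which the tests assert by
identifier tracking.

## Problem sizes and determinism

Defaults mirror the study protocol: n = 311 records, 4:1 splits, 10
repeats, 10-fold CV.  The test suite runs the stochastic checks at the
sizes the properties need — 200 seeds for coverage of coefficient
recovery, 50 seeds for generator calibration, 1000 covariate draws per
model for inversion identity, and two-repeat benchmarks with a subset of
algorithms where the full eight-way comparison adds nothing to the
property under test.  Every random draw flows from an explicit integer
seed through `numpy.random.default_rng`; identical seeds give
byte-identical CSV outputs (floats are serialized at 17 significant
digits).

## Known limitations

- Thresholds carry no uncertainty bands; the inversion treats fitted
  coefficients as exact.
- The CaCl₂/dissolved-pool proxies are statistical stand-ins, not
  geochemistry; conclusions about bioavailable-Cd thresholds on real
  soils require measured or modelled pools.
- The cleaning screen's mean ± 3 SD bound is sensitive to the planted
  or natural outlier mass because the SD is computed with outliers
  included (single pass, by design).
- Missing-data imputation from national soil databases, partial least
  squares path modelling, and surface-complexation speciation are
  documented inputs/context, not implemented features.
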