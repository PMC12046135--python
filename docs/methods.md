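# Methods

This note documents the statistical models implemented in `bagpa`, the
assumptions behind them, the synthetic cohort that exercises them, and the
numerical and design choices that were genuinely open.

## Brain-age model and bias correction

Brain age is predicted from IDP columns by gradient-boosted regression
trees (LightGBM) under K-fold cross-validation (default K = 10), so each
participant's prediction comes from a model never trained on them.
Defaults are 200 trees, learning rate 0.05, 15 leaves, `deterministic`
mode, single-threaded. An optional seeded random search (`hp_budget`
draws over learning rate, leaves, depth, subsampling, column sampling,
tree count) is scored on an inner validation split of the training fold
only; the default budget is 0 (fixed defaults), which is adequate on the
synthetic cohorts and keeps runs cheap.

Any regression of age on noisy features compresses predictions toward the
sample mean, inducing a spurious negative correlation between the raw gap
(predicted − chronological age) and age. The linear correction removes
it: with chronological age `x` and predicted age `y`, fit
`y = (a + 1)·x + b` by OLS and report `y − (a·x + b)`. The correction is
estimated *per fold on the training portion* and applied to the held-out
fold. The training-portion predictions used for the fit are themselves
out-of-fold (each comes from a model not trained on that participant), not
in-sample fits — in-sample predictions understate the
regression-to-the-mean slope. An in-test-fold variant
(`mode="test_fold"`) and no-correction mode exist for comparison.
Metrics are pooled across folds after correction.

MAE, R² and RMSE carry percentile-bootstrap 95% CIs over participant
resampling (default 5,000 replicates; simulation tests use fewer). R² is
computed as `1 − RMSE²/Var(age)`, identical to the usual sum-of-squares
form. Per-participant attributions use LightGBM's exact TreeSHAP
(`pred_contrib`), which satisfies local accuracy (base value + Σ
attributions = prediction) by construction; each participant is explained
by the model that held them out.

## Feature selection

Four stages, all fitted inside cross-validation folds:

1. **Screening.** Gain-based tree importance averaged over folds; top 50
   retained. Gain (not split count) is the conventional default; ties
   break by column order for determinism.
2. **Redundancy pruning.** The *supervised distance*
   `d(i, j) = 1 − |ρ_S(ŷ_i, ŷ_j)|`, where `ŷ_i` is the out-of-fold
   prediction of age from feature i alone (a depth-4 tree). Two features
   that carry the same information about the prediction task are close
   regardless of scale or shape. Complete-linkage hierarchical clustering
   is cut at 0.75; each cluster keeps its highest-importance member. A
   raw-correlation variant (`method="raw"`) supports sensitivity analysis.
   A constant feature has undefined prediction correlation and is placed
   at distance 1 from everything, with a warning.
3. **Permutation re-ranking.** Mean increase in held-out MAE when a
   feature's column is permuted (5 repeats per fold).
4. **Sequential forward selection.** Walk down the permutation ranking;
   retain a candidate only when the cross-validated MAE strictly
   decreases (margin ε, default 0), stop at 20 features. Every trial is
   recorded; the retained path is strictly decreasing by construction.

## Activity processing

Epoch magnitudes (mg) band as: light 30–125, moderate >125–400, vigorous
>400; below 30 mg counts toward no band; MVPA = MPA + VPA. Upper bounds
are closed (125 mg → LPA, 400 mg → MPA) by default and configurable,
since banding conventions differ on whether interval ends are open.
Minutes are rescaled to a 7-day week from observed wear time; traces under
72 h of wear fail QC. The 4-SD outlier rule is single-pass (mean and SD
frozen on the pre-exclusion vector), and a participant failing it on any
one metric is excluded from all analyses, reproducing a single
participant-flow count. Quartile cut points are empirical; boundary
values go to the lower quartile.

## Dose-response and scans

The GAM `BAG ~ s(PA) + COV` uses a thin-plate regression spline with REML
smoothing-parameter selection, fitted by mgcv through a batched Rscript
bridge — the reference implementation for penalized-smooth EDF and the
approximate F test. The basis size k is chosen from a grid (default
{5, 10, 15, 20}) by mgcv's residual-randomization adequacy check, taking
the first adequate k. EDF ≈ 1 indicates an effectively linear fit; the
null distribution of the smooth-term p-value is approximately uniform with
nominal 5% tail size (the mid-scale approximation error of the test is
documented in its calibration test). Fitted curves are reported on a
100-point exposure grid with covariates held at means/modes, ±1.96·SE.

Quartile contrasts are OLS of BAG on Q2–Q4 indicators (Q1 reference) plus
covariates, with Wald CIs. "Adjusted" Wilcoxon rank-sum and standardized
mean difference for Q4 vs Q1 are computed on BAG residualized against the
covariates — the paper-style contrast "after adjusting confounders" does
not specify a mechanism, so residualization is used and documented.

PA–IDP scans z-score both exposure and IDP (covariates unscaled) and
compute the standardized beta by Frisch–Waugh partialling — algebraically
identical to full OLS, verified against statsmodels in tests — plus an
optional GAM per pair. Benjamini–Hochberg correction is applied within
each exposure at α = 0.05.

## Mediation

The mediator model `BAG ~ PA + COV` (OLS) and outcome model
`outcome ~ PA + BAG + COV` (OLS, or logistic GLM for binary outcomes)
feed the simulation-based potential-outcomes algorithm (quasi-Bayesian
parameter draws, default 1,000; nonparametric bootstrap by flag): ACME,
ADE, total effect and proportion mediated with percentile CIs. No
exposure–mediator interaction is modeled, so ACME + ADE = total exactly in
the linear case. Binary outcomes are modeled as incident indicators with
effects on the risk-difference scale (simulated event probabilities),
which keeps the proportion mediated interpretable. Proportions are
reported signed — inconsistent mediation yields negative values — and the
screening table applies no multiplicity correction. The p-value for the
ACME is the two-sided sign-fraction of its draws.

## Synthetic cohort

The generator emulates the structure the analysis assumes, with planted
ground truth for recovery tests:

* **Age** uniform on 45–80 years (median ≈ 62).
* **Activity** log-normal per metric, parameterized by median and IQR
  targets (defaults: LPA 33.9 h/wk, MPA 7.73 h/wk, VPA 20.2 min/wk —
  right-skewed marginals typical of wrist accelerometry in late-middle
  age); MVPA is the derived sum.
* **True brain age** = age + curvature·(MVPA − optimum)² + α·MVPA −
  offset + N(0, σ), with σ = 3 y, curvature 0.015 y/(h/wk)², optimum
  8.2 h/wk (near the MVPA median: the dose-response bottoms out around
  typical activity), α = −0.06 y/(h/wk). The offset is computed
  analytically from the log-normal moments so the planted BAG has mean
  ≈ 0. With α ≠ 0 the planted curve's minimum shifts to
  optimum − α/(2·curvature); `planted_pa_optimum()` returns it.
* **IDPs.** Informative features are monotone views (half linear, half
  standardized tanh) of *independent additive components* of standardized
  true brain age (component sum = √m · standardized brain age, unit
  variance, zero pairwise correlation), plus N(0, 0.15) noise. Each
  feature alone is weakly informative (R² ≈ 1/m) while the full set
  determines brain age to ≈ noise·10.6 y ≈ 1.6 y — mirroring distinct
  brain structures that age along partially independent axes, and making
  redundancy pruning meaningful: distinct informative features sit at
  supervised distance ≈ 1 − 1/m, far above the 0.75 cut, whereas a
  single-latent design would place *all* informative features in one
  cluster and make selection recovery impossible. Redundant clusters
  replicate a parent informative IDP with N(0, 0.15) noise (pairwise
  |r| > 0.9); noise IDPs are standard normal.
* **Covariates** follow realistic categorical marginals (sex 55% female,
  97.6% white ethnicity, three-level education, smoking, six-level
  alcohol frequency, binary diet, Gaussian deprivation index). They are
  independent of activity by default; `covariate_pa_dependence=True`
  plants sex/education-driven confounding for adjustment tests.
* **Outcomes.** Continuous cognitive score = direct·MVPA + β·BAG + noise
  (direct −0.5, β 0.3 → planted proportion mediated
  αβ/(αβ + direct) ≈ 3.5%, a realistically small mediated share); a
  binary disorder uses a logistic link on the same predictor with
  intercept set from a 5% base rate.

What the generator does **not** emulate: raw 100-Hz triaxial signals,
device calibration or daylight-saving QC, spatial IDP covariance beyond
the planted clusters, non-Gaussian IDP noise, longitudinal follow-up, and
time-to-event disorder onset. Passing tests therefore demonstrate that
the *procedures* recover known structure under the stated model, not that
any specific real-cohort estimate is correct.

The planted ACME and proportion-mediated fields are exact only when
curvature = 0 (linear-linear); with a planted U-shape the linear mediator
model absorbs part of the quadratic. Mediation recovery tests use
linear-only configs accordingly.

## Numerical choices and degenerate inputs

* All stages are pure functions of (data, config, seed); the pipeline
  derives stage seeds as `sha256(stage:global_seed) mod 2^31` and no stage
  consumes ambient randomness. The mediation wrapper seeds NumPy's global
  generator because the underlying engine draws from it.
* Zero age variance in a correction fold, constant exposures, empty
  quartiles, rank-deficient covariate designs (aliased columns are
  named), non-finite features, and out-of-range p-values raise immediately.
* Constant IDP columns are skipped in scans with a warning; constant
  features get supervised distance 1.
* A zero-variance metric vector disables the 4-SD rule (everything
  retained); an all-identical quartile input is an error.
* Bootstrap CIs are percentile (simplest defensible default; bias-
  corrected variants were not needed at the tested sizes).
* Tests run the models at reduced sizes (e.g. n = 200–5,000, 50–500
  bootstrap or simulation replicates) chosen so each planted effect is
  comfortably detectable under its stated tolerance.

## Known limitations

* The GAM stage requires an R installation with mgcv; each call pays an
  interpreter-startup cost, amortized by batching (calibration tests and
  IDP scans run hundreds of fits in one session).
* The supervised-distance definition (correlation of single-feature
  out-of-fold predictions) is one reasonable formalization of
  target-aware redundancy; other definitions exist and the raw-correlation
  switch is provided for sensitivity analysis.
* Binary-outcome mediation treats incidence as a fixed indicator; no
  survival-time mediation, and no sensitivity analysis for sequential
  ignorability.
* LightGBM determinism holds for fixed library versions and thread count;
  the package pins neither.
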