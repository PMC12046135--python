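# bagpa

Brain-age-gap analysis of accelerometer-measured physical activity, as a
reusable, tested pipeline.

## The scientific problem

Structural brain MRI can be summarized into hundreds of image-derived
phenotypes (IDPs: regional volumes, cortical surface areas, thicknesses).
A regression model trained to predict chronological age from these IDPs
yields a *brain age*; the **brain age gap** (BAG) — bias-corrected
predicted age minus chronological age — is a compact marker of accelerated
or decelerated brain aging. A natural epidemiological question follows: is
objectively measured physical activity (PA, from wrist accelerometry)
associated with the BAG, and does the BAG mediate PA's effects on
cognition and incident brain disorders?

`bagpa` implements that full analysis for tabular cohorts:

1. **PA processing** (`bagpa.pa`) — weekly light / moderate / vigorous
   minutes from epoch-level acceleration magnitudes using the 30–125 mg /
   >125–400 mg / >400 mg bands (MVPA = MPA + VPA), a 72-h wear QC rule,
   a single-pass 4-SD outlier exclusion, and quartile assignment.
2. **Feature selection** (`bagpa.featsel`) — gradient-boosted tree
   importance screening to a top-50, *supervised-distance* redundancy
   pruning (complete-linkage clustering of `1 − |ρ|` between single-feature
   out-of-fold predictions, cut at 0.75), permutation re-ranking, and
   sequential forward selection to ≤ 20 features on cross-validated MAE.
3. **Brain age** (`bagpa.brainage`) — 10-fold cross-validated LightGBM
   prediction; per-fold linear age-bias correction: fit
   `y = (a + 1)·x + b` (x age, y predicted age) on the training portion's
   out-of-fold predictions and report `y − (a·x + b)` on the held-out
   fold; BAG = corrected age − age; MAE/R²/RMSE with percentile-bootstrap
   CIs; exact TreeSHAP attributions.
4. **Associations** (`bagpa.assoc`) — penalized thin-plate spline GAMs
   `BAG ~ s(PA) + COV` (REML smoothing, EDF, approximate F test, fitted
   curves with 95% CIs, fitted through mgcv), quartile OLS contrasts with
   covariate-adjusted Wilcoxon/SMD, mass PA–IDP scans with standardized
   betas and Benjamini–Hochberg FDR at α = 0.05.
5. **Mediation** (`bagpa.mediation`) — simulation-based potential-outcomes
   mediation (quasi-Bayesian draws): ACME, ADE, total effect, proportion
   mediated, for continuous and binary outcomes.
6. **Synthetic cohorts** (`bagpa.synthgen`) — a generator with planted,
   recoverable structure (age-dependent IDPs with redundant clusters,
   log-normal PA marginals, a planted U-shaped PA→BAG effect, mediation
   paths) so every stage is testable without access-controlled data.
7. **Orchestration** (`bagpa.pipeline`, CLI `bagpa`) — staged runs from a
   YAML config with deterministic seeds and a hash manifest.

## Worked example

```python
from bagpa import synthgen, brainage, assoc

cohort = synthgen.generate_cohort(synthgen.GenerativeConfig(n_participants=5000, seed=3))
res = brainage.brain_age_pipeline(
    cohort.table, cohort.truth.informative_idp_ids, folds=10,
    bootstrap_reps=500, seed=1,
)
print(f"MAE {res.metrics['mae'][0]:.2f} y  R2 {res.metrics['r2'][0]:.2f}  "
      f"rho(BAG, age) {res.spearman_bag_age_before:.2f} -> {res.spearman_bag_age_after:.2f}")

t = cohort.table.assign(bag=res.bag)
fit = assoc.fit_gam(t, "mvpa_h_wk", "bag", covariates=["age", "sex", "education", "townsend"])
print(f"s(MVPA): EDF {fit.edf:.2f}  F {fit.f_stat:.2f}  p {fit.p_value:.2g}  "
      f"curve minimum at {fit.argmin:.1f} h/week")
```

prints (exact values depend on the seeds):

```
MAE 2.63 y  R2 0.90  rho(BAG, age) -0.69 -> 0.00
s(MVPA): EDF 3.46  F 20.49  p 0  curve minimum at 10.1 h/week
```

The corrected MAE sits just above the irreducible floor
`σ·√(2/π) ≈ 2.39` years implied by the 3-year brain-age noise; the
Spearman correlation between BAG and age collapses from the
regression-to-the-mean artifact (−0.69) to ≈ 0 after correction; and the
GAM detects the planted U-shape (EDF ≫ 1) with its minimum near the
planted effect's optimum (10.2 h/week once the linear mediation path is
folded in; see `synthgen.planted_pa_optimum`).

The same analysis runs from the shell:

```bash
bagpa synth --n 5000 --seed 3 --out cohort.csv
bagpa run --config run.yaml     # staged pipeline with manifest
```

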