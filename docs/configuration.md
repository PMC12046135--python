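# Pipeline configuration

`bagpa run --config run.yaml` executes the staged pipeline. The YAML file
maps onto `bagpa.pipeline.RunConfig`:

```yaml
# run.yaml
input: synthetic          # or a path to a CSV/Parquet participant table
gen_config:               # only used when input == "synthetic"
  n_participants: 5000
  age_range: [45.0, 80.0]
  n_informative_idps: 15
  n_redundant_clusters: 5
  cluster_size: 3
  n_noise_idps: 300
  idp_noise_sd: 0.15
  brainage_noise_sd: 3.0
  u_shape: {pa_optimum: 8.2, curvature: 0.015}
  pa_medians: {lpa_h: 33.9, mpa_h: 7.73, vpa_min: 20.2}
  mediation: {alpha_pa_to_bag: -0.06, beta_bag_to_outcome: 0.30,
              direct_pa_to_outcome: -0.50}
  disorder_base_rate: 0.05
  seed: 0
stages: [pa, featsel, brainage, assoc, mediate]   # dependency order
output_dir: bagpa_run
global_seed: 1
stage_overrides:
  featsel:   {top_k: 50, threshold: 0.75, max_features: 20, cv_folds: 10}
  brainage:  {folds: 10, hp_budget: 0, bootstrap_reps: 5000,
              correction: train_fold}    # train_fold | test_fold | none
  assoc:     {k_grid: [5, 10, 15, 20]}
  mediate:   {n_sims: 1000,
              exposures: [lpa_h_wk, mpa_h_wk, vpa_min_wk, mvpa_h_wk],
              outcomes: {cognitive_score: continuous, disorder: binary}}
```

Stage dependencies are enforced: `brainage` needs the `featsel` output (or
an explicit `features` override), and `assoc`/`mediate` need the
`brainage` output (the BAG column). Stage seeds derive deterministically
from `global_seed`, and the run writes a `manifest.json` with input and
output content hashes — rerunning an identical config reproduces
identical hashes.

Input tables must carry: `participant_id`, `age`, the four weekly PA
summaries (`lpa_h_wk`, `mpa_h_wk`, `vpa_min_wk`, `mvpa_h_wk`), covariates
(`sex`, `ethnicity`, `education`, `townsend`, `smoking`, `alcohol`,
`diet`), IDP columns prefixed `idp_`, and outcome columns for the
mediation stage. Validation drops rows with missing covariates
(complete case) and applies the 4-SD activity exclusion before any stage
runs, recording a participant-flow summary.

A synthetic-cohort config alone (the `gen_config` block) can also be used
with `bagpa synth --config cohort.yaml --out cohort.csv`.
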