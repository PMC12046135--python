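"""End-to-end orchestration: input validation, staged analysis, manifest.

A run is driven by a :class:`RunConfig` (loadable from YAML).  The input is
either a participant table on disk or the synthetic generator.  Stages run
in dependency order (pa -> featsel -> brainage -> assoc -> mediate), each
writing versioned files into the output directory; the manifest records
input hashes, derived stage seeds and output hashes, so a rerun with the
same config reproduces identical hashes.

Stage seeds are derived deterministically from the global seed as
``sha256("<stage>:<global_seed>") mod 2^31`` — no stage consumes ambient
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bagpa import assoc, brainage, featsel, pa, synthgen
import bagpa.mediation as mediate_mod

logger = logging.getLogger("bagpa")

STAGES = ("pa", "featsel", "brainage", "assoc", "mediate")

DEFAULT_COVARIATES = [
    "age",
    "sex",
    "ethnicity",
    "education",
    "townsend",
    "smoking",
    "alcohol",
    "diet",
]
PA_METRICS = ["lpa_h_wk", "mpa_h_wk", "vpa_min_wk", "mvpa_h_wk"]


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    input: str = "synthetic"  # path to a table, or "synthetic"
    gen_config: synthgen.GenerativeConfig | None = None
    stages: tuple = STAGES
    output_dir: str = "bagpa_run"
    global_seed: int = 0
    stage_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.gen_config, dict):
            self.gen_config = synthgen.GenerativeConfig(**self.gen_config)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # enforce dependency order
        order = [s for s in STAGES if s in self.stages]
        if list(self.stages) != order:
            raise ValueError(f"stages must respect dependency order {STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class ValidationReport:
    missingness: pd.Series
    flow: list[tuple[str, int]]  # (step, n remaining)
    included: np.ndarray  # boolean mask over the input rows

    def to_dict(self) -> dict:
        return {
            "missingness": {k: float(v) for k, v in self.missingness.items()},
            "flow": [{"step": s, "n": int(n)} for s, n in self.flow],
            "n_included": int(self.included.sum()),
        }


def validate_input(
    table: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    pa_metrics=PA_METRICS,
    n_sd: float = 4.0,
) -> ValidationReport:
    """Participant-flow validation: missingness, complete-case covariates,
    and the per-metric 4-SD activity exclusion (a participant failing on
    any metric is dropped from all analyses)."""
    required = [c for c in list(covariates) + list(pa_metrics) if c in ("age",) or True]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise PipelineError(f"missing required columns: {missing_cols}")

    missingness = table[required].isna().mean()
    flow = [("input", len(table))]
    complete = ~table[list(covariates)].isna().any(axis=1)
    flow.append(("complete_covariates", int(complete.sum())))

    included = complete.to_numpy().copy()
    sub = table.loc[included]
    pa_mask = pa.combined_inclusion_mask(sub, pa_metrics, n_sd=n_sd)
    included[np.flatnonzero(included)] = pa_mask
    flow.append(("pa_4sd", int(included.sum())))
    return ValidationReport(missingness=missingness, flow=flow, included=included)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "input": config.input,
            "stages": list(config.stages),
            "global_seed": config.global_seed,
            "stage_overrides": config.stage_overrides,
            "gen_config": config.gen_config.to_dict() if config.gen_config else None,
        },
        "stages": {},
        "outputs": {},
    }

    t0 = time.time()
    if config.input == "synthetic":
        gen = config.gen_config or synthgen.GenerativeConfig(seed=stage_seed(config.global_seed, "synth"))
        cohort = synthgen.generate_cohort(gen)
        table = cohort.table
        input_path = _write_table(table, out_dir / "cohort.csv")
    else:
        input_path = Path(config.input)
        if not input_path.exists():
            raise PipelineError(f"input table not found: {input_path}")
        table = (
            pd.read_parquet(input_path)
            if input_path.suffix == ".parquet"
            else pd.read_csv(input_path)
        )
    manifest["input_hash"] = _sha256(input_path)
    logger.info("input ready (n=%d) in %.1fs", len(table), time.time() - t0)

    report = validate_input(table)
    table = table.loc[report.included].reset_index(drop=True)
    (out_dir / "validation.json").write_text(json.dumps(report.to_dict(), indent=1))
    manifest["outputs"]["validation.json"] = _sha256(out_dir / "validation.json")

    ctx: dict = {}
    for stage in config.stages:
        seed = stage_seed(config.global_seed, stage)
        over = dict(config.stage_overrides.get(stage, {}))
        t = time.time()
        manifest["stages"][stage] = {"seed": seed, "params": over}
        if stage == "pa":
            for m in PA_METRICS:
                table[f"{m}_quartile"] = pa.assign_quartiles(table[m].to_numpy())
            _write_table(table[["participant_id", *PA_METRICS, *[f"{m}_quartile" for m in PA_METRICS]]],
                         out_dir / "pa_summary.csv")
            manifest["outputs"]["pa_summary.csv"] = _sha256(out_dir / "pa_summary.csv")
        elif stage == "featsel":
            idps = [c for c in table.columns if c.startswith("idp_")]
            rep = featsel.run_feature_selection(
                table,
                idps,
                target="age",
                top_k=over.get("top_k", 50),
                threshold=over.get("threshold", 0.75),
                max_features=over.get("max_features", 20),
                cv_folds=over.get("cv_folds", 10),
                seed=seed,
            )
            rep.to_json(out_dir / "featsel_report.json")
            manifest["outputs"]["featsel_report.json"] = _sha256(out_dir / "featsel_report.json")
            ctx["final_set"] = rep.final_set
        elif stage == "brainage":
            features = over.get("features") or ctx.get("final_set")
            if features is None:
                fs_path = out_dir / "featsel_report.json"
                if fs_path.exists():
                    features = json.loads(fs_path.read_text())["final_set"]
                else:
                    raise PipelineError(
                        "brainage requires the featsel stage output or an explicit "
                        "'features' override; run the featsel stage first"
                    )
            result = brainage.brain_age_pipeline(
                table,
                features,
                folds=over.get("folds", 10),
                hp_budget=over.get("hp_budget", 0),
                bootstrap_reps=over.get("bootstrap_reps", 5000),
                correction=over.get("correction", "train_fold"),
                seed=seed,
            )
            table["bag"] = result.bag
            _write_table(result.to_frame(table), out_dir / "brainage.csv")
            payload = {
                "metrics": result.metrics,
                "metrics_uncorrected": result.metrics_uncorrected,
                "fold_corrections": result.fold_corrections,
                "spearman_bag_age_before": result.spearman_bag_age_before,
                "spearman_bag_age_after": result.spearman_bag_age_after,
                "features": result.features,
            }
            (out_dir / "brainage_metrics.json").write_text(json.dumps(payload, indent=1))
            manifest["outputs"]["brainage.csv"] = _sha256(out_dir / "brainage.csv")
            manifest["outputs"]["brainage_metrics.json"] = _sha256(out_dir / "brainage_metrics.json")
            ctx["bag"] = True
        elif stage in ("assoc", "mediate"):
            if "bag" not in table.columns:
                ba_path = out_dir / "brainage.csv"
                if ba_path.exists():
                    table["bag"] = pd.read_csv(ba_path)["bag"].to_numpy()
                else:
                    raise PipelineError(
                        f"{stage} requires the brainage stage output (BAG); run brainage first"
                    )
            covs = over.get("covariates", DEFAULT_COVARIATES)
            if stage == "assoc":
                gam_rows, quart_rows, curves = [], [], []
                for m in PA_METRICS:
                    fit = assoc.fit_gam(table, m, "bag", covariates=covs,
                                        k_grid=tuple(over.get("k_grid", assoc.DEFAULT_K_GRID)),
                                        seed=seed)
                    gam_rows.append(
                        {"exposure": m, "k": fit.k, "edf": fit.edf, "f_stat": fit.f_stat,
                         "p_value": fit.p_value, "argmin": fit.argmin}
                    )
                    c = fit.fitted_curve.copy()
                    c.insert(0, "exposure", m)
                    curves.append(c)
                    qcol = f"{m}_quartile"
                    q = table[qcol] if qcol in table.columns else pa.assign_quartiles(table[m].to_numpy())
                    qfit = assoc.fit_quartile_model(table, q, "bag", covariates=covs)
                    quart_rows.append(
                        {"exposure": m, "wilcoxon_p": qfit.wilcoxon_p, "smd": qfit.smd,
                         **{f"beta_{lev}": qfit.betas.loc[lev, "beta"] for lev in ("Q2", "Q3", "Q4")},
                         **{f"p_{lev}": qfit.betas.loc[lev, "p"] for lev in ("Q2", "Q3", "Q4")}}
                    )
                quart = pd.DataFrame(quart_rows)
                quart["wilcoxon_q"] = assoc.fdr_adjust(quart["wilcoxon_p"].to_numpy())
                pd.DataFrame(gam_rows).to_csv(out_dir / "assoc_gam.tsv", sep="\t", index=False)
                quart.to_csv(out_dir / "assoc_quartiles.tsv", sep="\t", index=False)
                pd.concat(curves).to_csv(out_dir / "assoc_curves.csv", index=False)
                for f in ("assoc_gam.tsv", "assoc_quartiles.tsv", "assoc_curves.csv"):
                    manifest["outputs"][f] = _sha256(out_dir / f)
            else:
                outcomes = over.get(
                    "outcomes", {"cognitive_score": "continuous", "disorder": "binary"}
                )
                screen = mediate_mod.mediation_screen(
                    table,
                    over.get("exposures", PA_METRICS),
                    outcomes,
                    mediator="bag",
                    covariates=covs,
                    n_sims=over.get("n_sims", 1000),
                    seed=seed,
                )
                screen.to_csv(out_dir / "mediation.tsv", sep="\t", index=False)
                manifest["outputs"]["mediation.tsv"] = _sha256(out_dir / "mediation.tsv")
        logger.info("stage %s done in %.1fs", stage, time.time() - t)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
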