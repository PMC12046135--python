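"""Subprocess bridge to the mgcv GAM engine.

Penalized-spline GAMs (thin-plate basis, REML smoothing-parameter
selection, EDF and the approximate F test for the smooth term) are fitted
by mgcv through an Rscript call.  Several datasets can be stacked into one
call to amortize interpreter startup, which matters for simulation-based
calibration tests and for IDP scans.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from importlib import resources
from pathlib import Path

import pandas as pd

_DATASET_COL = "__dataset__"


class MgcvError(RuntimeError):
    pass


def _script_path() -> Path:
    return Path(resources.files("bagpa") / "resources" / "gam_fit.R")


def fit_gam_mgcv(
    frames: list[pd.DataFrame],
    exposure: str,
    outcome: str,
    covariates=(),
    factor_covariates=(),
    k_grid=(10,),
    n_grid: int = 100,
    curve: bool = True,
    seed: int = 0,
) -> list[dict]:
    """Fit one GAM per frame; returns one result dict per frame.

    Each frame must contain ``exposure``, ``outcome`` and all covariate
    columns.  A per-frame failure is returned as ``{"error": ...}`` rather
    than aborting the batch.
    """
    if not frames:
        return []
    stacked = []
    for i, df in enumerate(frames):
        d = df[[outcome, exposure, *covariates, *factor_covariates]].copy()
        d[_DATASET_COL] = i
        stacked.append(d)
    data = pd.concat(stacked, ignore_index=True)

    spec = {
        "exposure": exposure,
        "outcome": outcome,
        "covariates": list(covariates) + list(factor_covariates),
        "factor_covariates": list(factor_covariates),
        "k_grid": list(k_grid),
        "n_grid": n_grid,
        "curve": curve,
        "seed": int(seed) % (2**31),
        "dataset_col": _DATASET_COL if len(frames) > 1 else None,
    }

    with tempfile.TemporaryDirectory(prefix="bagpa_mgcv_") as tmp:
        tmp = Path(tmp)
        data_csv = tmp / "data.csv"
        spec_json = tmp / "spec.json"
        out_json = tmp / "out.json"
        data.to_csv(data_csv, index=False)
        spec_json.write_text(json.dumps(spec))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_script_path()), str(data_csv), str(spec_json), str(out_json)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_json.exists():
            raise MgcvError(f"mgcv fit failed:\n{proc.stderr[-2000:]}")
        results = json.loads(out_json.read_text())
    if len(frames) == 1:
        return results
    # restore input order (ids may round-trip as strings or floats)
    by_id = {int(float(r.get("dataset"))): r for r in results}
    return [by_id[i] for i in range(len(frames))]
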