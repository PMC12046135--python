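"""Accelerometer physical-activity processing.

Weekly intensity summaries are derived from epoch-level average acceleration
magnitudes (milligravities, mg) using the wrist-accelerometer banding
convention: light activity (LPA) between 30 and 125 mg, moderate (MPA)
above 125 up to 400 mg, vigorous (VPA) above 400 mg; epochs below 30 mg
are sedentary and count toward no band.  MVPA is the sum of moderate and
vigorous minutes.  Traces with less than 72 h of wear fail quality control.

Boundary epochs (exactly 125 or 400 mg) are assigned to the lower band by
default; pass ``boundary="open_upper"`` for the alternative convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SEDENTARY_CUT_MG = 30.0
LPA_UPPER_MG = 125.0
MPA_UPPER_MG = 400.0
MIN_WEAR_HOURS = 72.0
WEEK_MINUTES = 7 * 24 * 60.0

__all__ = [
    "PASummary",
    "classify_epochs",
    "exclude_outliers",
    "combined_inclusion_mask",
    "assign_quartiles",
]


@dataclass(frozen=True)
class PASummary:
    """Weekly physical-activity minutes by intensity band, plus wear QC."""

    lpa_min_wk: float
    mpa_min_wk: float
    vpa_min_wk: float
    mvpa_min_wk: float
    wear_hours: float
    qc_pass: bool

    def __post_init__(self) -> None:
        if min(self.lpa_min_wk, self.mpa_min_wk, self.vpa_min_wk) < 0:
            raise ValueError("PA minute fields must be non-negative")
        if abs(self.mvpa_min_wk - (self.mpa_min_wk + self.vpa_min_wk)) > 1e-9:
            raise ValueError("mvpa_min_wk must equal mpa_min_wk + vpa_min_wk")


def classify_epochs(
    magnitudes,
    epoch_s: float,
    *,
    boundary: str = "closed_upper",
) -> PASummary:
    """Band epoch magnitudes into weekly LPA/MPA/VPA minutes.

    Minutes are scaled to a 7-day week from the observed wear time
    (``n_epochs * epoch_s``); a trace spanning exactly 7 days is returned
    unscaled.

    Parameters
    ----------
    magnitudes : array-like of float
        Per-epoch average acceleration magnitude in mg. Must be non-empty
        and non-negative.
    epoch_s : float
        Epoch duration in seconds.
    boundary : {"closed_upper", "open_upper"}
        Whether band upper bounds are inclusive (125 mg -> LPA, 400 mg ->
        MPA; default) or exclusive.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.size == 0:
        raise ValueError("empty epoch trace: no wear data")
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if np.any(mags < 0) or not np.all(np.isfinite(mags)):
        raise ValueError("magnitudes must be finite and non-negative")
    if boundary not in ("closed_upper", "open_upper"):
        raise ValueError(f"unknown boundary convention: {boundary!r}")

    if boundary == "closed_upper":
        lpa = (mags >= SEDENTARY_CUT_MG) & (mags <= LPA_UPPER_MG)
        mpa = (mags > LPA_UPPER_MG) & (mags <= MPA_UPPER_MG)
        vpa = mags > MPA_UPPER_MG
    else:
        lpa = (mags >= SEDENTARY_CUT_MG) & (mags < LPA_UPPER_MG)
        mpa = (mags >= LPA_UPPER_MG) & (mags < MPA_UPPER_MG)
        vpa = mags >= MPA_UPPER_MG

    wear_min = mags.size * epoch_s / 60.0
    wear_hours = wear_min / 60.0
    scale = WEEK_MINUTES / wear_min
    epoch_min = epoch_s / 60.0

    lpa_min = float(lpa.sum()) * epoch_min * scale
    mpa_min = float(mpa.sum()) * epoch_min * scale
    vpa_min = float(vpa.sum()) * epoch_min * scale
    return PASummary(
        lpa_min_wk=lpa_min,
        mpa_min_wk=mpa_min,
        vpa_min_wk=vpa_min,
        mvpa_min_wk=mpa_min + vpa_min,
        wear_hours=wear_hours,
        qc_pass=wear_hours >= MIN_WEAR_HOURS,
    )


def exclude_outliers(values, n_sd: float = 4.0) -> np.ndarray:
    """Single-pass mean +/- ``n_sd``-SD inclusion mask for one PA metric.

    The mean and SD are computed once on the full vector before any
    exclusion (no iterative re-fitting), so the rule is idempotent on its
    retained set only in the trivial sense.  A zero-variance vector retains
    every observation.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or np.sum(np.isfinite(v)) < 2:
        raise ValueError("need at least 2 finite values")
    mean = np.nanmean(v)
    sd = np.nanstd(v, ddof=1)
    if sd == 0:
        return np.ones(v.shape, dtype=bool)
    return np.abs(v - mean) <= n_sd * sd


def combined_inclusion_mask(table: pd.DataFrame, metrics, n_sd: float = 4.0) -> np.ndarray:
    """Participant-level mask: excluded if *any* PA metric fails the SD rule."""
    mask = np.ones(len(table), dtype=bool)
    for col in metrics:
        mask &= exclude_outliers(table[col].to_numpy(), n_sd=n_sd)
    return mask


def assign_quartiles(values) -> np.ndarray:
    """Label observations Q1-Q4 by empirical quartile cut points.

    Boundary values (exactly on a cut point) go to the lower quartile.
    Raises if fewer than 4 distinct values or if any quartile would be
    empty under the tie policy.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.unique(v).size < 4:
        raise ValueError("need at least 4 distinct values to form quartiles")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    idx = (v > cuts[0]).astype(int) + (v > cuts[1]) + (v > cuts[2])
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])[idx]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 4:
        missing = sorted({"Q1", "Q2", "Q3", "Q4"} - set(counts.index))
        raise ValueError(f"quartile group(s) empty under tie policy: {missing}")
    return labels
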