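"""Association of physical activity with the brain age gap and with IDPs.

Nonlinear dose-response is modeled as ``BAG ~ s(PA) + COV`` — a penalized
thin-plate regression spline for the activity term plus linear covariate
terms, smoothing parameter chosen by REML, basis size k chosen from a grid
by a residual-randomization adequacy check.  The smooth's effective
degrees of freedom (EDF) quantify nonlinearity (EDF near 1 means an
effectively linear fit) and the approximate F test gives its p-value.

Linear dose-response uses activity quartiles (Q1 reference) in OLS with
covariates, plus a Wilcoxon rank-sum test and standardized mean difference
for Q4 vs Q1 computed on covariate-residualized BAG.

The PA-IDP scan fits, per (exposure, IDP) pair, a linear model on z-scored
exposure and z-scored IDP with covariates (standardized beta, via
Frisch-Waugh residualization for speed) and optionally the GAM; p-values
are Benjamini-Hochberg adjusted within each exposure at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bagpa._design import covariate_matrix
from bagpa._mgcv import fit_gam_mgcv

__all__ = [
    "GAMFit",
    "QuartileModelFit",
    "fit_gam",
    "fit_quartile_model",
    "scan_idp_associations",
    "fdr_adjust",
]

DEFAULT_K_GRID = (5, 10, 15, 20)


@dataclass
class GAMFit:
    """A fitted penalized-spline smooth of BAG on a PA metric."""

    exposure: str
    outcome: str
    k: int
    edf: float
    ref_df: float
    f_stat: float
    p_value: float
    penalty: float  # REML-selected smoothing parameter
    r_sq: float
    n: int
    covariate_coefs: pd.DataFrame
    fitted_curve: pd.DataFrame  # columns x, fit, lo, hi

    @property
    def argmin(self) -> float:
        """Exposure value minimizing the fitted curve (the estimated optimum)."""
        c = self.fitted_curve
        return float(c["x"].iloc[int(np.argmin(c["fit"].to_numpy()))])


def _split_covariates(table: pd.DataFrame, covariates):
    numeric, factor = [], []
    for c in covariates:
        s = table[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            factor.append(c)
        else:
            numeric.append(c)
    return numeric, factor


def fit_gam(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates=(),
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    n_grid: int = 100,
) -> GAMFit:
    """Fit ``outcome ~ s(exposure) + covariates`` by penalized REML smoothing."""
    cols = [exposure, outcome, *covariates]
    d = table[cols].dropna()
    if d.empty:
        raise ValueError("no complete rows for the requested columns")
    # fail early, with names, on aliased covariates
    covariate_matrix(d, covariates)
    numeric, factor = _split_covariates(d, covariates)
    res = fit_gam_mgcv(
        [d],
        exposure=exposure,
        outcome=outcome,
        covariates=numeric,
        factor_covariates=factor,
        k_grid=tuple(k_grid),
        n_grid=n_grid,
        seed=seed,
    )[0]
    if "error" in res:
        raise RuntimeError(f"GAM fit failed: {res['error']}")
    curve = pd.DataFrame(res["curve"])
    return GAMFit(
        exposure=exposure,
        outcome=outcome,
        k=int(res["k"]),
        edf=float(res["edf"]),
        ref_df=float(res["ref_df"]),
        f_stat=float(res["f_stat"]),
        p_value=float(res["p_value"]),
        penalty=float(res["sp"]),
        r_sq=float(res["r_sq"]),
        n=int(res["n"]),
        covariate_coefs=pd.DataFrame(res["parametric"]),
        fitted_curve=curve,
    )


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


@dataclass
class QuartileModelFit:
    """OLS of BAG on PA quartile indicators (Q1 reference) plus covariates."""

    betas: pd.DataFrame  # index Q1..Q4: beta, lo, hi, p (Q1 row is the 0 reference)
    wilcoxon_p: float  # Q4 vs Q1 rank-sum on covariate-adjusted BAG
    smd: float  # standardized mean difference, Q4 vs Q1, adjusted
    fdr_q: float | None = None


def fit_quartile_model(
    table: pd.DataFrame,
    quartiles,
    outcome: str,
    covariates=(),
) -> QuartileModelFit:
    import statsmodels.api as sm

    q = np.asarray(quartiles)
    y = table[outcome].to_numpy(dtype=float)
    levels = ["Q1", "Q2", "Q3", "Q4"]
    for lev in levels:
        if not np.any(q == lev):
            raise ValueError(f"empty quartile group {lev}")
    C = covariate_matrix(table, covariates).to_numpy(dtype=float)
    dummies = np.column_stack([(q == lev).astype(float) for lev in levels[1:]])
    X = np.column_stack([C, dummies])
    names = list(covariate_matrix(table, covariates).columns) + ["Q2", "Q3", "Q4"]
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    ci = fit.conf_int()
    rows = [{"quartile": "Q1", "beta": 0.0, "lo": 0.0, "hi": 0.0, "p": np.nan}]
    for lev in levels[1:]:
        rows.append(
            {
                "quartile": lev,
                "beta": float(fit.params[lev]),
                "lo": float(ci.loc[lev, 0]),
                "hi": float(ci.loc[lev, 1]),
                "p": float(fit.pvalues[lev]),
            }
        )
    betas = pd.DataFrame(rows).set_index("quartile")

    resid = _residualize(y, C)
    r1, r4 = resid[q == "Q1"], resid[q == "Q4"]
    wil = stats.mannwhitneyu(r4, r1, alternative="two-sided").pvalue
    pooled = np.sqrt(
        ((r4.size - 1) * r4.var(ddof=1) + (r1.size - 1) * r1.var(ddof=1)) / (r4.size + r1.size - 2)
    )
    smd = float((r4.mean() - r1.mean()) / pooled) if pooled > 0 else 0.0
    return QuartileModelFit(betas=betas, wilcoxon_p=float(wil), smd=smd)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan_idp_associations(
    table: pd.DataFrame,
    exposures,
    idp_columns,
    covariates=(),
    alpha: float = 0.05,
    include_gam: bool = False,
    k_grid=(10,),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(exposure, IDP) standardized linear betas, optionally GAM terms,
    BH-adjusted within each exposure.

    The linear model regresses the z-scored IDP on the z-scored exposure
    plus covariates; the standardized beta, its Wald CI and p-value are
    computed by Frisch-Waugh partialling (identical to the full OLS).
    Constant IDP columns are skipped with a warning.
    """
    idp_columns = list(idp_columns)
    C = covariate_matrix(table, covariates).to_numpy(dtype=float)
    n, p_cov = C.shape

    idps = table[idp_columns].to_numpy(dtype=float)
    sd = idps.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        skipped = list(np.array(idp_columns)[~keep])
        warnings.warn(f"skipping constant IDP columns: {skipped}")
    idp_cols_used = list(np.array(idp_columns)[keep])
    Z = (idps[:, keep] - idps[:, keep].mean(axis=0)) / sd[keep]
    Zr = Z - C @ np.linalg.lstsq(C, Z, rcond=None)[0]

    rows = []
    for exposure in exposures:
        x = table[exposure].to_numpy(dtype=float)
        xz = (x - x.mean()) / x.std(ddof=1)
        xr = _residualize(xz, C)
        sxx = float(xr @ xr)
        beta = Zr.T @ xr / sxx
        resid = Zr - np.outer(xr, beta)
        dof = n - p_cov - 1
        sigma2 = np.sum(resid**2, axis=0) / dof
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        pvals = 2 * stats.t.sf(np.abs(tstat), dof)
        tcrit = stats.t.ppf(0.975, dof)
        q = fdr_adjust(pvals)

        gam_res = [None] * len(idp_cols_used)
        if include_gam:
            frames = [
                pd.DataFrame({"idp_value": table[c].to_numpy(dtype=float), exposure: x, **{
                    cv: table[cv].to_numpy() for cv in covariates
                }})
                for c in idp_cols_used
            ]
            numeric, factor = _split_covariates(table, covariates)
            gam_res = fit_gam_mgcv(
                frames,
                exposure=exposure,
                outcome="idp_value",
                covariates=numeric,
                factor_covariates=factor,
                k_grid=tuple(k_grid),
                curve=False,
                seed=seed,
            )
        for j, c in enumerate(idp_cols_used):
            row = {
                "exposure": exposure,
                "idp": c,
                "beta": float(beta[j]),
                "lo": float(beta[j] - tcrit * se[j]),
                "hi": float(beta[j] + tcrit * se[j]),
                "p": float(pvals[j]),
                "q": float(q[j]),
                "significant": bool(q[j] <= alpha),
            }
            g = gam_res[j]
            if g is not None and "error" not in g:
                row.update(
                    edf=float(g["edf"]), f_stat=float(g["f_stat"]), p_gam=float(g["p_value"])
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    if include_gam and "p_gam" in out.columns:
        out["q_gam"] = np.nan
        for exposure in exposures:
            m = (out["exposure"] == exposure) & out["p_gam"].notna()
            out.loc[m, "q_gam"] = fdr_adjust(out.loc[m, "p_gam"].to_numpy())
    return out
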