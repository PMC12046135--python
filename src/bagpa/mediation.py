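"""Causal mediation of activity -> brain-health effects through the BAG.

The estimand decomposition follows the simulation-based potential-outcomes
algorithm (Imai-Keele-Tingley): a linear mediator model
``BAG ~ exposure + covariates`` and an outcome model
``outcome ~ exposure + BAG + covariates`` (OLS for continuous outcomes,
logistic GLM for binary ones) are fitted, parameter vectors are drawn from
their estimated sampling distributions (quasi-Bayesian draws; a
nonparametric bootstrap is available via ``method="bootstrap"``), potential
mediator and outcome values are simulated, and effect contrasts averaged:
ACME (the path through the BAG), ADE (the direct path), their total, and
the proportion mediated ACME / total.  For binary outcomes the potential
outcomes are event probabilities, so effects are risk differences.

No exposure-mediator interaction is modeled, hence ACME + ADE = total
exactly in the linear-linear case.  Proportions mediated are reported
signed (inconsistent mediation yields negative values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.mediation import Mediation

from bagpa._design import covariate_matrix

__all__ = ["MediationEstimate", "mediate", "mediation_screen"]


@dataclass
class MediationEstimate:
    exposure: str
    outcome: str
    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    proportion_mediated: float
    proportion_ci: tuple[float, float]
    p_acme: float
    n_sims: int
    outcome_family: str
    estimable: bool = True
    note: str = ""

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "acme": self.acme,
            "acme_lo": self.acme_ci[0],
            "acme_hi": self.acme_ci[1],
            "ade": self.ade,
            "ade_lo": self.ade_ci[0],
            "ade_hi": self.ade_ci[1],
            "total": self.total,
            "total_lo": self.total_ci[0],
            "total_hi": self.total_ci[1],
            "proportion_mediated": self.proportion_mediated,
            "proportion_lo": self.proportion_ci[0],
            "proportion_hi": self.proportion_ci[1],
            "p_acme": self.p_acme,
            "n_sims": self.n_sims,
            "outcome_family": self.outcome_family,
            "estimable": self.estimable,
            "note": self.note,
        }


def _pvalue_from_draws(draws: np.ndarray) -> float:
    if np.min(draws) > 0 or np.max(draws) < 0:
        return 2 * min((draws < 0).mean(), (draws > 0).mean()) + 2.0 / len(draws)
    return 2 * min((draws < 0).mean(), (draws > 0).mean())


def mediate(
    table: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates=(),
    n_sims: int = 1000,
    seed: int = 0,
    outcome_family: str = "continuous",
    method: str = "parametric",
) -> MediationEstimate:
    """Estimate ACME / ADE / total effect / proportion mediated.

    ``method="parametric"`` draws model parameters from their asymptotic
    sampling distribution (quasi-Bayesian); ``"bootstrap"`` refits on
    resampled data.  Deterministic given ``seed``.
    """
    cols = [exposure, mediator, outcome, *covariates]
    d = table[cols].dropna().reset_index(drop=True)
    if d[mediator].nunique() <= 2:
        raise ValueError("binary mediators are unsupported; the BAG mediator is continuous")
    if d[exposure].nunique() < 2:
        raise ValueError(f"exposure {exposure!r} is constant; mediation not estimable")

    C = covariate_matrix(d, covariates)  # includes the intercept
    X_med = pd.concat([d[[exposure]], C], axis=1)
    X_out = pd.concat([d[[exposure, mediator]], C], axis=1)
    med_model = sm.OLS(d[mediator], X_med)
    if outcome_family == "continuous":
        out_model = sm.OLS(d[outcome], X_out)
    elif outcome_family == "binary":
        out_model = sm.GLM(d[outcome], X_out, family=sm.families.Binomial())
    else:
        raise ValueError(f"unknown outcome_family: {outcome_family!r}")

    # statsmodels' Mediation draws from the global NumPy RNG
    np.random.seed(int(seed) % (2**31))
    try:
        res = Mediation(out_model, med_model, exposure, mediator).fit(
            method=method, n_rep=n_sims
        )
    except np.linalg.LinAlgError as e:
        raise RuntimeError(f"mediation models not estimable: {e}") from e
    except Exception as e:  # e.g. perfect separation in the logistic model
        if "separation" in str(e).lower():
            raise RuntimeError(f"separation in the logistic outcome model: {e}") from e
        raise

    acme_draws = np.asarray(res.ACME_avg)
    ade_draws = np.asarray(res.ADE_avg)
    total_draws = np.asarray(res.total_effect)
    prop_draws = np.asarray(res.prop_med_avg)
    acme = float(acme_draws.mean())
    ade = float(ade_draws.mean())
    total = float(total_draws.mean())
    prop = acme / total if total != 0 else float("nan")

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return MediationEstimate(
        exposure=exposure,
        outcome=outcome,
        acme=acme,
        acme_ci=ci(acme_draws),
        ade=ade,
        ade_ci=ci(ade_draws),
        total=total,
        total_ci=ci(total_draws),
        proportion_mediated=float(prop),
        proportion_ci=ci(prop_draws[np.isfinite(prop_draws)]),
        p_acme=float(_pvalue_from_draws(acme_draws)),
        n_sims=n_sims,
        outcome_family=outcome_family,
    )


def mediation_screen(
    table: pd.DataFrame,
    exposures,
    outcomes,
    mediator: str,
    covariates=(),
    n_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One mediation estimate per exposure x outcome pair.

    ``outcomes`` maps outcome column -> family ("continuous" or "binary").
    Per-pair failures become flagged rows (``estimable = False``) rather
    than aborting the screen.  Rows are ordered by the ACME p-value; no
    multiplicity correction is applied.
    """
    rows = []
    for i, exposure in enumerate(exposures):
        for j, (outcome, family) in enumerate(dict(outcomes).items()):
            pair_seed = (int(seed) + 7919 * i + 104729 * j) % (2**31)
            try:
                est = mediate(
                    table,
                    exposure,
                    mediator,
                    outcome,
                    covariates=covariates,
                    n_sims=n_sims,
                    seed=pair_seed,
                    outcome_family=family,
                )
                rows.append(est.to_row())
            except (ValueError, RuntimeError) as e:
                rows.append(
                    {
                        "exposure": exposure,
                        "outcome": outcome,
                        "outcome_family": family,
                        "estimable": False,
                        "note": str(e),
                        "p_acme": np.nan,
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values("p_acme", na_position="last").reset_index(drop=True)
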