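"""Synthetic cohort generator with planted, recoverable effects.

The generator emulates the statistical structure a brain-age / physical-
activity analysis assumes, at configurable scale:

* chronological age uniform over a mid-to-late-life range;
* a latent *true brain age* equal to age plus a planted physical-activity
  effect (a U-shaped term in weekly MVPA hours plus an optional linear
  mediation path) and Gaussian noise;
* informative IDP columns that are noisy monotone functions (half linear,
  half saturating) of *independent additive components* of standardized
  true brain age — mirroring distinct brain structures that age along
  partially independent axes, so each feature alone is weakly informative
  while the full set determines brain age precisely; redundant clusters
  replicate an informative IDP with small independent noise; pure-noise
  IDPs are independent of age;
* right-skewed (log-normal) weekly activity summaries parameterized by
  median/IQR targets;
* covariates with realistic categorical marginals;
* a continuous cognitive outcome and a binary incident-disorder indicator
  carrying a planted mediation structure (activity -> BAG -> outcome).

The U-shape and mediation offsets are centered analytically so the planted
brain-age gap has mean approximately zero.  Ground truth (informative
feature ids, redundant groups, true brain age/gap, planted mediation
effects) is returned alongside the table for parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UShape",
    "PAMedians",
    "MediationPaths",
    "GenerativeConfig",
    "CohortTruth",
    "SyntheticCohort",
    "EpochTrace",
    "generate_cohort",
    "generate_epoch_trace",
]

# quartile z-spread of the standard normal; ln(q3/q1) = sigma * _IQR_Z
_IQR_Z = 1.3489795003921634

PA_COLUMNS = ("lpa_h_wk", "mpa_h_wk", "vpa_min_wk", "mvpa_h_wk")
COVARIATE_COLUMNS = (
    "sex",
    "ethnicity",
    "education",
    "townsend",
    "smoking",
    "alcohol",
    "diet",
)


@dataclass(frozen=True)
class UShape:
    """Planted U-shaped MVPA -> brain-age effect (minimum at the optimum)."""

    pa_optimum: float = 8.2  # h/week of MVPA
    curvature: float = 0.015  # years per (h/week)^2


@dataclass(frozen=True)
class PAMedians:
    """Weekly activity medians (and IQRs) the log-normal marginals target."""

    lpa_h: float = 33.9
    mpa_h: float = 7.73
    vpa_min: float = 20.2
    lpa_h_iqr: tuple[float, float] = (29.4, 38.8)
    mpa_h_iqr: tuple[float, float] = (5.54, 10.4)
    vpa_min_iqr: tuple[float, float] = (10.1, 40.3)


@dataclass(frozen=True)
class MediationPaths:
    """Planted mediation paths: activity -> BAG (alpha), BAG -> outcome
    (beta), and the direct activity -> outcome path."""

    alpha_pa_to_bag: float = -0.06  # years per h/week MVPA
    beta_bag_to_outcome: float = 0.30  # outcome units per year of BAG
    direct_pa_to_outcome: float = -0.50  # outcome units per h/week MVPA


@dataclass
class GenerativeConfig:
    n_participants: int = 5000
    age_range: tuple[float, float] = (45.0, 80.0)
    n_informative_idps: int = 15
    n_redundant_clusters: int = 5
    cluster_size: int = 3
    n_noise_idps: int = 300
    idp_noise_sd: float = 0.15
    brainage_noise_sd: float = 3.0
    u_shape: UShape = field(default_factory=UShape)
    pa_medians: PAMedians = field(default_factory=PAMedians)
    mediation: MediationPaths = field(default_factory=MediationPaths)
    disorder_base_rate: float = 0.05
    outcome_noise_sd: float = 1.0
    redundant_noise_sd: float = 0.15
    covariate_pa_dependence: bool = False
    max_idp_columns: int = 1425
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.u_shape, dict):
            self.u_shape = UShape(**self.u_shape)
        if isinstance(self.pa_medians, dict):
            self.pa_medians = PAMedians(**self.pa_medians)
        if isinstance(self.mediation, dict):
            self.mediation = MediationPaths(**self.mediation)
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        for name in ("n_participants", "n_informative_idps", "n_redundant_clusters", "cluster_size", "n_noise_idps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_redundant_clusters > 0 and self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2 when redundant clusters are requested")
        if self.n_redundant_clusters > self.n_informative_idps:
            raise ValueError("cannot have more redundant clusters than informative IDPs")
        if not 0.0 < self.disorder_base_rate < 1.0:
            raise ValueError("disorder_base_rate must lie in (0, 1)")
        if self.u_shape.curvature < 0:
            raise ValueError("U-shape curvature must be >= 0")
        n_cols = self.n_informative_idps + self.n_redundant_clusters * self.cluster_size + self.n_noise_idps
        if n_cols > self.max_idp_columns:
            raise ValueError(
                f"requested {n_cols} IDP columns exceeds the column budget of {self.max_idp_columns}"
            )

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class CohortTruth:
    informative_idp_ids: list[str]
    redundant_groups: list[list[str]]
    true_brain_age: np.ndarray
    true_bag: np.ndarray
    planted_acme: float
    planted_proportion_mediated: float

    def to_json(self, path) -> None:
        payload = {
            "informative_idp_ids": self.informative_idp_ids,
            "redundant_groups": self.redundant_groups,
            "true_brain_age": np.asarray(self.true_brain_age).tolist(),
            "true_bag": np.asarray(self.true_bag).tolist(),
            "planted_acme": self.planted_acme,
            "planted_proportion_mediated": self.planted_proportion_mediated,
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SyntheticCohort:
    table: pd.DataFrame
    truth: CohortTruth
    config: GenerativeConfig

    @property
    def idp_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("idp_")]

    def write(self, table_path, truth_path=None) -> None:
        path = Path(table_path)
        if path.suffix == ".parquet":
            self.table.to_parquet(path, index=False)
        else:
            self.table.to_csv(path, index=False)
        if truth_path is not None:
            self.truth.to_json(truth_path)


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    q1, q3 = iqr
    if not (0 < q1 < q3):
        raise ValueError("IQR bounds must be positive and ordered")
    sigma = math.log(q3 / q1) / _IQR_Z
    return math.log(median), sigma


def _lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    mean = math.exp(mu + sigma**2 / 2)
    var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
    return mean, var


def mvpa_population_moments(cfg: GenerativeConfig) -> tuple[float, float]:
    """Analytic mean and variance of weekly MVPA hours under the config."""
    pm = cfg.pa_medians
    m_mu, m_sig = _lognormal_params(pm.mpa_h, pm.mpa_h_iqr)
    v_mu, v_sig = _lognormal_params(pm.vpa_min, pm.vpa_min_iqr)
    m_mean, m_var = _lognormal_moments(m_mu, m_sig)
    v_mean, v_var = _lognormal_moments(v_mu, v_sig)
    return m_mean + v_mean / 60.0, m_var + v_var / 3600.0


def planted_pa_optimum(cfg: GenerativeConfig) -> float:
    """MVPA value minimizing the planted activity -> brain-age curve.

    The planted effect is curvature * (x - pa_optimum)^2 + alpha * x (up to
    constants), so its minimum sits at pa_optimum - alpha / (2 * curvature)
    when the linear mediation path alpha is nonzero.
    """
    u, a = cfg.u_shape, cfg.mediation.alpha_pa_to_bag
    if u.curvature == 0:
        raise ValueError("no U-shape planted (curvature = 0)")
    return u.pa_optimum - a / (2.0 * u.curvature)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # marginals mirror a middle-aged UK accelerometry cohort
    edu = rng.choice(
        ["higher_education", "no_qualification", "other_qualification"],
        size=n,
        p=[0.502, 0.054, 0.444],
    )
    smoking = rng.choice(["never", "previous", "current"], size=n, p=[0.628, 0.338, 0.034])
    alcohol = rng.choice(
        ["daily", "3_4_per_week", "1_2_per_week", "1_3_per_month", "special", "never"],
        size=n,
        p=[0.182, 0.279, 0.258, 0.117, 0.105, 0.059],
    )
    return pd.DataFrame(
        {
            "sex": rng.choice(["female", "male"], size=n, p=[0.552, 0.448]),
            "ethnicity": rng.choice(["white", "non_white"], size=n, p=[0.976, 0.024]),
            "education": edu,
            "townsend": rng.normal(-2.2, 2.6, size=n),
            "smoking": smoking,
            "alcohol": alcohol,
            "diet": rng.choice(["healthy", "unhealthy"], size=n, p=[0.603, 0.397]),
        }
    )


def generate_cohort(config: GenerativeConfig) -> SyntheticCohort:
    """Draw a deterministic synthetic cohort under ``config``.

    See the module docstring for the generative model.  The same seed
    yields a bit-identical table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    pm = cfg.pa_medians
    lpa_mu, lpa_sig = _lognormal_params(pm.lpa_h, pm.lpa_h_iqr)
    mpa_mu, mpa_sig = _lognormal_params(pm.mpa_h, pm.mpa_h_iqr)
    vpa_mu, vpa_sig = _lognormal_params(pm.vpa_min, pm.vpa_min_iqr)
    lpa_h = rng.lognormal(lpa_mu, lpa_sig, size=n)
    mpa_h = rng.lognormal(mpa_mu, mpa_sig, size=n)
    vpa_min = rng.lognormal(vpa_mu, vpa_sig, size=n)

    covs = _draw_covariates(rng, n)
    if cfg.covariate_pa_dependence:
        # deliberate confounding: men and higher-educated participants
        # are planted as more active
        shift = 0.15 * (covs["sex"].to_numpy() == "male") + 0.10 * (
            covs["education"].to_numpy() == "higher_education"
        )
        mpa_h = mpa_h * np.exp(shift - shift.mean())
        vpa_min = vpa_min * np.exp(shift - shift.mean())

    mvpa_h = mpa_h + vpa_min / 60.0
    mvpa_mean, mvpa_var = mvpa_population_moments(cfg)

    u = cfg.u_shape
    med = cfg.mediation
    # analytic centering so the planted BAG has mean ~ 0
    u_offset = u.curvature * ((mvpa_mean - u.pa_optimum) ** 2 + mvpa_var)
    mvpa_dev = mvpa_h - mvpa_mean
    planted = (
        u.curvature * (mvpa_h - u.pa_optimum) ** 2
        - u_offset
        + med.alpha_pa_to_bag * mvpa_dev
    )
    true_brain_age = age + planted + rng.normal(0.0, cfg.brainage_noise_sd, size=n)
    true_bag = true_brain_age - age

    # IDPs: noisy monotone views of independent components of standardized
    # true brain age.  Components c_j satisfy sum_j c_j = sqrt(m) * tba_z,
    # have ~unit variance and ~zero pairwise correlation, so each feature
    # alone explains only ~1/m of the age signal while the full set
    # recovers it up to the per-feature noise.
    tba_z = (true_brain_age - true_brain_age.mean()) / true_brain_age.std()
    idp = {}
    informative_ids = []
    m = cfg.n_informative_idps
    if m > 0:
        eps = rng.normal(0.0, 1.0, size=(n, m))
        eps -= eps.mean(axis=1, keepdims=True)
        comps = tba_z[:, None] / math.sqrt(m) + eps
    for j in range(m):
        name = f"idp_info_{j:03d}"
        informative_ids.append(name)
        c = comps[:, j]
        if j % 2 == 0:
            signal = c
        else:
            shift = ((j // 2) % 3 - 1) * 0.6
            signal = 1.6 * np.tanh(0.9 * (c + shift))
            signal = (signal - signal.mean()) / signal.std()
        idp[name] = signal + rng.normal(0.0, cfg.idp_noise_sd, size=n)

    redundant_groups: list[list[str]] = []
    for c in range(cfg.n_redundant_clusters):
        parent = informative_ids[c]
        group = [parent]
        for r in range(cfg.cluster_size):
            name = f"idp_red_{c:02d}_{r}"
            idp[name] = idp[parent] + rng.normal(0.0, cfg.redundant_noise_sd, size=n)
            group.append(name)
        redundant_groups.append(group)

    for j in range(cfg.n_noise_idps):
        idp[f"idp_noise_{j:03d}"] = rng.normal(0.0, 1.0, size=n)

    # outcomes with planted mediation structure (exposure = MVPA h/week)
    cognitive = (
        med.direct_pa_to_outcome * mvpa_dev
        + med.beta_bag_to_outcome * true_bag
        + rng.normal(0.0, cfg.outcome_noise_sd, size=n)
    )
    intercept = math.log(cfg.disorder_base_rate / (1 - cfg.disorder_base_rate))
    lp = intercept + med.direct_pa_to_outcome * mvpa_dev + med.beta_bag_to_outcome * true_bag
    disorder = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)

    table = pd.DataFrame({"participant_id": np.arange(n), "age": age})
    table["lpa_h_wk"] = lpa_h
    table["mpa_h_wk"] = mpa_h
    table["vpa_min_wk"] = vpa_min
    table["mvpa_h_wk"] = mvpa_h
    table = pd.concat([table, covs], axis=1)
    table["cognitive_score"] = cognitive
    table["disorder"] = disorder
    idp_df = pd.DataFrame(idp)
    table = pd.concat([table, idp_df], axis=1)

    denom = med.alpha_pa_to_bag * med.beta_bag_to_outcome + med.direct_pa_to_outcome
    planted_acme = med.alpha_pa_to_bag * med.beta_bag_to_outcome
    prop = planted_acme / denom if denom != 0 else float("nan")
    truth = CohortTruth(
        informative_idp_ids=informative_ids,
        redundant_groups=redundant_groups,
        true_brain_age=true_brain_age,
        true_bag=true_bag,
        planted_acme=planted_acme,
        planted_proportion_mediated=prop,
    )
    return SyntheticCohort(table=table, truth=truth, config=cfg)


@dataclass
class EpochTrace:
    """A synthetic epoch-level accelerometer trace with wear metadata."""

    magnitudes: np.ndarray
    epoch_s: float
    wear_hours: float


def generate_epoch_trace(
    weekly_minutes: dict,
    epoch_s: float = 60.0,
    seed: int = 0,
    wear_hours: float = 168.0,
) -> EpochTrace:
    """Build an epoch trace whose banding recovers the requested minutes.

    ``weekly_minutes`` maps ``{"lpa": ..., "mpa": ..., "vpa": ...}`` to
    weekly minute targets; remaining wear time is filled with sedentary
    epochs (< 30 mg).  With the default 168 h of wear the weekly scaling
    factor is exactly 1, so re-classification is an exact round trip.
    Shorter ``wear_hours`` (e.g. 71.9) produce traces that fail wear QC.
    """
    if epoch_s <= 0 or 60 % epoch_s != 0:
        raise ValueError("epoch_s must be positive and divide 60")
    per_min = int(round(60 / epoch_s))
    counts = {}
    for band in ("lpa", "mpa", "vpa"):
        minutes = float(weekly_minutes.get(band, 0))
        if minutes < 0:
            raise ValueError("weekly minutes must be non-negative")
        n_epochs = minutes * per_min
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValueError(f"{band} minutes not representable with epoch_s={epoch_s}")
        counts[band] = int(round(n_epochs))
    total_epochs = wear_hours * 3600.0 / epoch_s
    if abs(total_epochs - round(total_epochs)) > 1e-6:
        raise ValueError("wear_hours not an integer number of epochs")
    total_epochs = int(round(total_epochs))
    n_active = sum(counts.values())
    if n_active > total_epochs:
        raise ValueError("requested activity exceeds wear time")

    rng = np.random.default_rng(seed)
    mags = np.concatenate(
        [
            rng.uniform(35.0, 120.0, size=counts["lpa"]),
            rng.uniform(130.0, 395.0, size=counts["mpa"]),
            rng.uniform(405.0, 900.0, size=counts["vpa"]),
            rng.uniform(0.0, 25.0, size=total_epochs - n_active),
        ]
    )
    rng.shuffle(mags)
    return EpochTrace(magnitudes=mags, epoch_s=epoch_s, wear_hours=wear_hours)
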