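"""Synthetic patient cohorts with planted outcome and survival structure.

The simulator emulates the statistical shape of a two-centre high-risk DLBCL
cohort: binary clinical covariates at specified marginal frequencies,
log-normal metabolic metrics (SUVmax / MTV / TLG), a 110-column radiomic
feature block, a binary mid-term outcome (non-CR) whose log-odds depend on a
named subset of features and covariates, and exponential PFS/OS times whose
hazard depends on the latent radiomic score group. Every quantity flows from
a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .features.catalogue import ALL_FEATURE_NAMES, KEY_FEATURE_CODES

__all__ = ["CohortSpec", "simulate_cohort", "split_cohort", "DEFAULT_COVARIATE_MARGINS"]

logger = logging.getLogger(__name__)

#: marginal frequencies of the binary clinical covariates (pooled cohort)
DEFAULT_COVARIATE_MARGINS: dict[str, float] = {
    "sex": 129 / 177,              # male
    "age_ge60": 96 / 177,
    "ldh_elevated": 35 / 177,
    "b_symptoms": 58 / 177,
    "ecog_ge2": 145 / 177,
    "ipi_ge3": 37 / 177,
    "nccn_ipi_68": 25 / 177,
    "stage_34": 158 / 177,
    "extranodal_ge2": 47 / 177,
    "bone_marrow": 128 / 177,
    "bulky": 67 / 177,
    "gcb": 100 / 177,
}

_KEY_FEATURES = [n for n in ALL_FEATURE_NAMES if n.split(".")[1] in KEY_FEATURE_CODES]

#: planted log-odds: a radiomic signal on key features plus sex/B-symptoms/SUVmax
DEFAULT_LOG_ODDS: dict[str, float] = {
    _KEY_FEATURES[0]: 0.8,   # shape surface area
    _KEY_FEATURES[2]: 0.7,   # global intensity peak
    _KEY_FEATURES[6]: 0.6,   # GLCM joint maximum
    "sex": 0.55,
    "b_symptoms": 0.75,
    "suvmax_log_z": 0.5,
}


@dataclass
class CohortSpec:
    """Cohort generator settings (defaults emulate the study conditions)."""

    n: int = 177
    prevalence: float = 0.40          # marginal non-CR rate
    covariate_margins: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINS)
    )
    log_odds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    feature_names: list[str] = field(default_factory=lambda: list(ALL_FEATURE_NAMES))
    # metabolic metric distributions: lognormal sigma + printed dichotomization margins
    suvmax_cutoff: float = 19.2
    suvmax_frac_above: float = 79 / 177
    suvmax_sigma: float = 0.5
    mtv_cutoff: float = 25.6
    mtv_frac_above: float = 128 / 177
    mtv_sigma: float = 1.0
    # survival model: exponential hazards by latent-score group
    pfs_baseline_hazard: float = 0.020   # events per month, low-score group
    os_baseline_hazard: float = 0.012
    pfs_log_hr: float = math.log(2.17)
    os_log_hr: float = math.log(2.14)
    followup_months: tuple[float, float] = (18.0, 42.0)  # administrative censoring window
    censoring_rate: float = 0.10         # extra early-dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring rate must be in [0, 1)")
        if self.n < 10:
            raise ValueError("n must be >= 10")


def _lognormal(rng, n, sigma, cutoff, frac_above):
    """Log-normal draws calibrated so P(X >= cutoff) = frac_above."""
    mu = math.log(cutoff) - sigma * ndtri(1.0 - frac_above)
    return np.exp(rng.normal(mu, sigma, size=n))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort as a feature table (one row per patient).

    Columns: patient id, binary clinical covariates, continuous SUVmax / MTV /
    TLG, the radiomic feature block (standard-normal unless planted), the
    binary ``outcome`` (1 = non-CR), a ``true_score`` column holding the
    latent radiomic linear predictor, and PFS/OS times (months) with event
    flags.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})

    for name, p in spec.covariate_margins.items():
        df[name] = (rng.random(n) < p).astype(int)

    suvmax = _lognormal(rng, n, spec.suvmax_sigma, spec.suvmax_cutoff, spec.suvmax_frac_above)
    mtv = _lognormal(rng, n, spec.mtv_sigma, spec.mtv_cutoff, spec.mtv_frac_above)
    suvmean = 0.5 * suvmax * np.exp(rng.normal(0.0, 0.2, size=n))
    df["suvmax"] = suvmax
    df["mtv_cm3"] = mtv
    df["tlg"] = suvmean * mtv

    feats = pd.DataFrame(
        rng.standard_normal((n, len(spec.feature_names))), columns=spec.feature_names
    )
    df = pd.concat([df, feats], axis=1)

    # derived column available to the planted model
    logsuv = np.log(suvmax)
    df["suvmax_log_z"] = (logsuv - logsuv.mean()) / logsuv.std()

    unknown = [k for k in spec.log_odds if k not in df.columns]
    if unknown:
        raise KeyError(f"log-odds coefficient(s) on unknown column(s): {', '.join(unknown)}")

    linpred = np.zeros(n)
    rad_score = np.zeros(n)
    for name, beta in spec.log_odds.items():
        contrib = beta * df[name].to_numpy(dtype=float)
        linpred += contrib
        if name in spec.feature_names:
            rad_score += contrib
    df["true_score"] = rad_score

    # intercept solved so the marginal outcome rate matches the prevalence
    def gap(alpha: float) -> float:
        return float(expit(alpha + linpred).mean()) - spec.prevalence

    alpha = brentq(gap, -30.0, 30.0)
    df["outcome"] = (rng.random(n) < expit(alpha + linpred)).astype(int)

    # survival: exponential hazards by high/low latent-score group
    group = (rad_score >= np.median(rad_score)).astype(int) if rad_score.any() else np.zeros(n, dtype=int)
    df["true_group_high"] = group
    admin = rng.uniform(*spec.followup_months, size=n)
    dropout = (rng.random(n) < spec.censoring_rate)
    drop_time = rng.uniform(0.0, admin)
    censor = np.where(dropout, np.minimum(admin, drop_time), admin)
    for prefix, lam0, loghr in (
        ("pfs", spec.pfs_baseline_hazard, spec.pfs_log_hr),
        ("os", spec.os_baseline_hazard, spec.os_log_hr),
    ):
        lam = lam0 * np.exp(loghr * group)
        t_event = rng.exponential(1.0 / lam)
        observed = np.minimum(t_event, censor)
        df[f"{prefix}_months"] = observed
        df[f"{prefix}_event"] = (t_event <= censor).astype(int)

    df.drop(columns=["suvmax_log_z"], inplace=True)
    return df


def split_cohort(
    table: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/validation split; validation size is
    ``ceil(n * test_fraction)`` (177 at 0.3 gives 123/54)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(table)
    n_val = math.ceil(n * test_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    train = table.iloc[train_idx].reset_index(drop=True)
    val = table.iloc[val_idx].reset_index(drop=True)
    if "outcome" in table.columns and train["outcome"].nunique() < 2:
        logger.warning("training split contains a single outcome class")
    return train, val
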