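"""Outcome-prediction layer: Youden cutoffs, logistic odds ratios, the five
prediction models, ROC/AUC with DeLong intervals, bootstrap calibration,
decision-curve analysis, nomogram points and cohort-comparison chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "CutoffResult",
    "youden_cutoff",
    "delong_auc_ci",
    "LogisticResult",
    "univariate_logistic",
    "multivariate_logistic",
    "screen_univariate",
    "PredictionModel",
    "MODEL_VARIABLES",
    "build_models",
    "calibration_bootstrap",
    "dca",
    "nomogram_points",
    "cohort_chisq",
    "chisq_from_table",
]


# ------------------------------------------------------------- ROC / Youden

def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (structural components)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)
    r_pos, r_neg = ranks[:m], ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_pos - stats.rankdata(pos)) / n - auc  # structural components, positives
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m - auc
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    return float(auc), float(var)


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong-type normal-approximation confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, var = _delong_variance(scores, labels)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal dichotomization of one continuous variable."""

    variable: str
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(scores, labels, variable: str = "score") -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct observed
    scores (rule: predicted positive when score >= threshold); ties in J are
    broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("constant scores admit no cutoff")
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for t in thresholds:  # ascending, so first max is the lowest threshold
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / n_pos)
        spec = float((~pred & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    auc, lo, hi = delong_auc_ci(scores, labels)
    j, t, sens, spec = best
    return CutoffResult(variable=variable, auc=auc, auc_ci=(lo, hi), threshold=float(t),
                        sensitivity=sens, specificity=spec, youden_j=float(j))


# ------------------------------------------------------------- logistic ORs

@dataclass
class LogisticResult:
    """Odds ratios with Wald CIs from a maximum-likelihood logistic fit."""

    variables: list[str]
    table: pd.DataFrame          # index: variable; columns: or, ci_low, ci_high, coef, p
    params: pd.Series            # includes the intercept
    model: object = field(repr=False, default=None)

    def odds_ratio(self, variable: str) -> float:
        return float(self.table.loc[variable, "or"])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[self.variables], has_constant="add")
        return np.asarray(self.model.predict(Xd))


def _fit_logistic(cohort: pd.DataFrame, variables: list[str], outcome: str) -> LogisticResult:
    missing = [v for v in variables + [outcome] if v not in cohort.columns]
    if missing:
        raise KeyError(f"missing column(s): {', '.join(missing)}")
    y = cohort[outcome].astype(float)
    X = sm.add_constant(cohort[variables].astype(float), has_constant="add")
    n_events = int(y.sum())
    if min(n_events, len(y) - n_events) < 10 * len(variables):
        warnings.warn(
            f"fewer than 10 outcome events per variable ({n_events} events, "
            f"{len(variables)} variables); estimates may be unstable",
            stacklevel=3,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"logistic fit failed (possible perfect separation): {exc}") from exc
    fitted = res.predict(X)
    if np.any(fitted > 1 - 1e-10) or np.any(fitted < 1e-10):
        raise ValueError("perfect separation detected: fitted probabilities at 0/1")
    ci = res.conf_int()
    table = pd.DataFrame({
        "coef": res.params[variables],
        "or": np.exp(res.params[variables]),
        "ci_low": np.exp(ci.loc[variables, 0]),
        "ci_high": np.exp(ci.loc[variables, 1]),
        "p": res.pvalues[variables],
    })
    return LogisticResult(variables=list(variables), table=table, params=res.params, model=res)


def univariate_logistic(cohort: pd.DataFrame, variable: str, outcome: str = "outcome") -> LogisticResult:
    return _fit_logistic(cohort, [variable], outcome)


def multivariate_logistic(cohort: pd.DataFrame, variables: list[str], outcome: str = "outcome") -> LogisticResult:
    return _fit_logistic(cohort, list(variables), outcome)


def screen_univariate(
    cohort: pd.DataFrame, variables: list[str], outcome: str = "outcome", alpha: float = 0.05
) -> list[str]:
    """Variables whose univariate logistic p-value is below ``alpha`` (the
    entry rule for the multivariate model)."""
    kept = []
    for v in variables:
        try:
            res = univariate_logistic(cohort, v, outcome)
        except ValueError:
            continue
        if float(res.table.loc[v, "p"]) < alpha:
            kept.append(v)
    return kept


# ------------------------------------------------------------- model set

#: the five prediction models and their predictor columns (dichotomized
#: SUVmax and RadScore at their Youden cutoffs)
MODEL_VARIABLES: dict[str, list[str]] = {
    "combined": ["sex", "b_symptoms", "suvmax_high", "radscore_high"],
    "clinical": ["sex", "b_symptoms"],
    "pet": ["suvmax_high"],
    "nccn_ipi": ["nccn_ipi_68"],
    "ipi": ["ipi_ge3"],
}


@dataclass
class PredictionModel:
    name: str
    result: LogisticResult
    auc_train: float
    auc_validation: float | None = None


def build_models(
    train: pd.DataFrame,
    validation: pd.DataFrame | None = None,
    outcome: str = "outcome",
    model_variables: dict[str, list[str]] | None = None,
) -> dict[str, PredictionModel]:
    """Fit the five logistic prediction models and evaluate their AUCs."""
    model_variables = model_variables or MODEL_VARIABLES
    out = {}
    for name, variables in model_variables.items():
        res = multivariate_logistic(train, variables, outcome)
        auc_tr = float(roc_auc_score(train[outcome], res.predict(train)))
        auc_val = None
        if validation is not None:
            auc_val = float(roc_auc_score(validation[outcome], res.predict(validation)))
        out[name] = PredictionModel(name=name, result=res, auc_train=auc_tr, auc_validation=auc_val)
    return out


# ------------------------------------------------------------- calibration

def calibration_bootstrap(
    predicted: np.ndarray,
    observed: np.ndarray,
    reps: int = 1000,
    n_bins: int = 10,
    seed: int = 0,
) -> dict:
    """Decile-binned observed-vs-predicted calibration, averaged over
    bootstrap resamples; slope/intercept from regressing observed on
    predicted bin means. ``reps=1`` is the apparent (unresampled) curve."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(predicted)

    def one_curve(p, o):
        order = np.argsort(p)
        bins = np.array_split(order, n_bins)
        pts = [(p[b].mean(), o[b].mean()) for b in bins if len(b)]
        return np.array(pts)

    curves = []
    for r in range(reps):
        if reps == 1:
            p, o = predicted, observed
        else:
            idx = rng.integers(0, n, size=n)
            p, o = predicted[idx], observed[idx]
        curves.append(one_curve(p, o))
    curve = np.mean(np.stack(curves), axis=0)
    slope, intercept, *_ = stats.linregress(curve[:, 0], curve[:, 1])
    return {
        "curve": pd.DataFrame(curve, columns=["predicted", "observed"]),
        "slope": float(slope),
        "intercept": float(intercept),
        "reps": reps,
    }


# ------------------------------------------------------------- DCA

def dca(predicted, observed, thresholds=None) -> pd.DataFrame:
    """Decision-curve analysis: net benefit of classifying at predicted-risk
    >= p_t, against treat-all and treat-none references.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(observed)
    prevalence = observed.mean()
    rows = []
    for pt in thresholds:
        w = pt / (1.0 - pt)
        pred_pos = predicted >= pt
        tp = float((pred_pos & (observed == 1)).sum()) / n
        fp = float((pred_pos & (observed == 0)).sum()) / n
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * w,
            "treat_all": prevalence - (1.0 - prevalence) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------- nomogram

def nomogram_points(result: LogisticResult, X: pd.DataFrame) -> dict:
    """Nomogram point scales for a fitted logistic model.

    Each variable's points are proportional to |coefficient| x observed range,
    with the largest effect spanning 0-100; the total-points axis maps back to
    predicted risk through the inverse logit, so reading the nomogram agrees
    with the model probability.
    """
    coefs = result.params[result.variables]
    ranges = {}
    for v in result.variables:
        lo, hi = float(X[v].min()), float(X[v].max())
        if hi == lo:
            hi = lo + 1.0
        ranges[v] = (lo, hi)
    spans = {v: abs(coefs[v]) * (ranges[v][1] - ranges[v][0]) for v in result.variables}
    max_span = max(spans.values())
    if max_span == 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    scale = 100.0 / max_span  # points per unit of |beta * x|

    tables = {}
    base = 0.0  # linear-predictor offset at the zero-point anchors
    for v in result.variables:
        lo, hi = ranges[v]
        beta = float(coefs[v])
        anchor = lo if beta >= 0 else hi  # variable value at 0 points
        base += beta * anchor
        grid = np.linspace(lo, hi, 11)
        pts = np.abs(beta) * np.abs(grid - anchor) * scale
        tables[v] = pd.DataFrame({"value": grid, "points": pts})

    intercept = float(result.params["const"]) + base

    def risk_at_total(total_points: float) -> float:
        lp = intercept + np.asarray(total_points, dtype=float) / scale
        return 1.0 / (1.0 + np.exp(-lp))

    def points_for(record: pd.Series) -> float:
        total = 0.0
        for v in result.variables:
            beta = float(coefs[v])
            anchor = ranges[v][0] if beta >= 0 else ranges[v][1]
            total += abs(beta) * abs(float(record[v]) - anchor) * scale
        return total

    return {
        "per_variable": tables,
        "scale_points_per_lp": scale,
        "risk_at_total": risk_at_total,
        "points_for": points_for,
    }


# ------------------------------------------------------------- chi-square

def chisq_from_table(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a contingency
    table; raises on zero expected cells."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count")
    return float(chi2), float(p)


def cohort_chisq(train: pd.DataFrame, validation: pd.DataFrame, variable: str) -> tuple[float, float]:
    """Compare one categorical variable between cohorts (train vs validation)."""
    levels = sorted(set(train[variable].unique()) | set(validation[variable].unique()))
    table = np.array([
        [int((train[variable] == lv).sum()) for lv in levels],
        [int((validation[variable] == lv).sum()) for lv in levels],
    ])
    return chisq_from_table(table)
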