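"""Selector x classifier cross-combination engine and the RadScore.

Seven machine-learning methods — GBDT, ET, RF, AdaBoost, LASSO, SVM, LR —
are crossed as feature selectors against the same seven as classifiers
(49 pairs). For each pair, stratified five-fold cross-validation is run with
feature selection repeated inside every training fold (leakage-safe);
the pair with the largest mean held-out AUC is elected and refit on the full
training cohort to yield the RadScore: a weighted sum of the selected,
standardized radiomic features.

The engine follows the modelling-object idiom: ``CrossCombination(X, y)``
is the model, ``.fit()`` returns a :class:`CrossCombinationResults` carrying
the AUC matrix, the elected pair and the fitted :class:`RadScoreModel`, with
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "METHODS",
    "make_method",
    "rank_features",
    "select_features",
    "evaluate_pair",
    "RadScoreModel",
    "fit_radscore",
    "CrossCombination",
    "CrossCombinationResults",
]

#: the seven methods, in upstream listing order (used for tie-breaks)
METHODS = ("GBDT", "ET", "RF", "AdaBoost", "LASSO", "SVM", "LR")

#: light, fixed hyperparameters; echoed into run manifests
HYPERPARAMS = {
    "GBDT": {"n_estimators": 50, "max_depth": 2},
    "ET": {"n_estimators": 50},
    "RF": {"n_estimators": 50},
    "AdaBoost": {"n_estimators": 50},
    "LASSO": {"penalty": "l1", "C": 1.0, "solver": "liblinear"},
    "SVM": {"C": 1.0, "selector_kernel": "linear", "classifier_kernel": "rbf"},
    "LR": {"penalty": "l2", "C": 1.0},
}


def make_method(method: str, role: str = "classifier", seed: int = 0):
    """Instantiate one of the seven methods for the given role.

    As selectors, SVM uses a linear kernel (coefficients are needed) and
    LASSO a fixed penalty; as a classifier, LASSO is an L1-penalized
    logistic regression with a small CV-chosen penalty grid and SVM an RBF
    machine scored through its decision function.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if role not in ("selector", "classifier"):
        raise ValueError("role must be 'selector' or 'classifier'")
    if method == "GBDT":
        return GradientBoostingClassifier(n_estimators=50, max_depth=2, random_state=seed)
    if method == "ET":
        return ExtraTreesClassifier(n_estimators=50, random_state=seed)
    if method == "RF":
        return RandomForestClassifier(n_estimators=50, random_state=seed)
    if method == "AdaBoost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if method == "LASSO":
        if role == "classifier":
            return LogisticRegressionCV(
                l1_ratios=[1.0], solver="liblinear", Cs=[0.01, 0.1, 1.0, 10.0],
                cv=3, scoring="roc_auc", max_iter=2000, random_state=seed,
                use_legacy_attributes=False,
            )
        return LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                  max_iter=2000, random_state=seed)
    if method == "SVM":
        kernel = "linear" if role == "selector" else "rbf"
        return SVC(kernel=kernel, C=1.0, random_state=seed)
    return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)


def _decision_scores(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def _method_weights(est) -> np.ndarray:
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_, dtype=float).ravel())
    raise AttributeError(f"{type(est).__name__} exposes neither importances nor coefficients")


def _signed_weights(est) -> np.ndarray | None:
    if hasattr(est, "coef_"):
        return np.asarray(est.coef_, dtype=float).ravel()
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    return None


def rank_features(method: str, X: pd.DataFrame, y, seed: int = 0) -> pd.Series:
    """Non-negative per-feature weights from one fitted selection model."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    est = make_method(method, role="selector", seed=seed)
    est.fit(X.to_numpy(), y)
    return pd.Series(_method_weights(est), index=X.columns)


def _cv_auc(method: str, X: np.ndarray, y: np.ndarray, cv: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = make_method(method, role="selector", seed=seed)
        est.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _decision_scores(est, X[te])))
    return float(np.mean(aucs))


def select_features(
    method: str,
    X: pd.DataFrame,
    y,
    cv: int = 3,
    seed: int = 0,
    step: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive elimination: repeatedly drop the lowest-weight feature(s),
    recording the method's CV AUC on each subset; return the subset with the
    largest AUC (ties broken toward the smaller subset) plus the full trace.
    """
    y = np.asarray(y)
    names = list(X.columns)
    if len(names) < 1:
        raise ValueError("need at least one feature")
    trace = []
    while names:
        sub = X[names].to_numpy()
        auc = _cv_auc(method, sub, y, cv, seed) if len(np.unique(y)) > 1 else 0.5
        est = make_method(method, role="selector", seed=seed)
        est.fit(sub, y)
        weights = _method_weights(est)
        trace.append({"n_features": len(names), "features": tuple(names), "cv_auc": auc})
        if len(names) == 1:
            break
        order = np.argsort(weights, kind="stable")
        drop = {names[i] for i in order[: min(step, len(names) - 1)]}
        names = [n for n in names if n not in drop]
    trace_df = pd.DataFrame(trace)
    best_auc = trace_df["cv_auc"].max()
    candidates = trace_df[trace_df["cv_auc"] >= best_auc - 1e-12]
    best = candidates.loc[candidates["n_features"].idxmin()]
    return list(best["features"]), trace_df


@dataclass
class _Standardizer:
    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "_Standardizer":
        std = X.std(ddof=0).replace(0.0, 1.0)
        return cls(mean=X.mean(), std=std)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean) / self.std


def evaluate_pair(
    selector: str,
    classifier: str,
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    selection_cv: int = 3,
    step: int = 1,
) -> tuple[float, list[float]]:
    """Mean held-out AUC of one selector-classifier pair under stratified
    k-fold CV, with standardization and selection redone inside each
    training fold (no leakage)."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr, te in skf.split(X, y):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        scaler = _Standardizer.fit(Xtr)
        Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
        selected, _ = select_features(selector, Xtr_s, y[tr], cv=selection_cv,
                                      seed=seed, step=step)
        clf = make_method(classifier, role="classifier", seed=seed)
        clf.fit(Xtr_s[selected].to_numpy(), y[tr])
        fold_aucs.append(roc_auc_score(y[te], _decision_scores(clf, Xte_s[selected].to_numpy())))
    return float(np.mean(fold_aucs)), [float(a) for a in fold_aucs]


@dataclass
class RadScoreModel:
    """Weighted-sum radiomic score over the selected, standardized features.

    ``score(x) = sum_i w_i * z_i`` where ``z_i`` standardizes feature ``i``
    with the stored training statistics. Dichotomization cutoffs (mid-term
    outcome, PFS, OS) are attached once chosen by the Youden rule.
    """

    feature_names: list[str]
    weights: np.ndarray
    mean: pd.Series
    std: pd.Series
    selector: str
    classifier: str
    weight_source: str = "classifier"
    cutoffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if len(self.weights) != len(self.feature_names):
            raise ValueError("one weight per selected feature required")

    def score(self, X: pd.DataFrame | pd.Series) -> np.ndarray | float:
        single = isinstance(X, pd.Series)
        frame = X.to_frame().T if single else X
        missing = [n for n in self.feature_names if n not in frame.columns]
        if missing:
            raise KeyError(f"record is missing selected feature(s): {', '.join(missing)}")
        z = (frame[self.feature_names] - self.mean[self.feature_names]) / self.std[self.feature_names]
        s = z.to_numpy() @ self.weights
        return float(s[0]) if single else s

    def as_dict(self) -> dict:
        return {
            "selector": self.selector,
            "classifier": self.classifier,
            "weight_source": self.weight_source,
            "features": list(self.feature_names),
            "weights": [float(w) for w in self.weights],
            "cutoffs": dict(self.cutoffs),
        }


def fit_radscore(
    X: pd.DataFrame,
    y,
    selector: str,
    classifier: str,
    seed: int = 0,
    selection_cv: int = 3,
    step: int = 1,
    weight_source: str = "classifier",
) -> RadScoreModel:
    """Refit the elected pair on the full training cohort and build the score.

    Weights default to the classifier's refit coefficients (importances for
    tree ensembles); ``weight_source="selector"`` uses the selection model's
    weights instead. An RBF-kernel SVM classifier exposes no per-feature
    coefficients, in which case the selector's weights are used.
    """
    y = np.asarray(y)
    scaler = _Standardizer.fit(X)
    Xs = scaler.transform(X)
    selected, _ = select_features(selector, Xs, y, cv=selection_cv, seed=seed, step=step)

    sel_est = make_method(selector, role="selector", seed=seed)
    sel_est.fit(Xs[selected].to_numpy(), y)
    weights = _signed_weights(sel_est)
    source = "selector"
    if weight_source == "classifier":
        clf = make_method(classifier, role="classifier", seed=seed)
        clf.fit(Xs[selected].to_numpy(), y)
        w = _signed_weights(clf)
        if w is not None:
            weights, source = w, "classifier"
    if weights is None or not np.any(weights):
        raise ValueError("degenerate RadScore: all weights zero")
    return RadScoreModel(
        feature_names=list(selected),
        weights=weights,
        mean=scaler.mean,
        std=scaler.std,
        selector=selector,
        classifier=classifier,
        weight_source=source,
    )


class CrossCombination:
    """The 7x7 selector-by-classifier model-election protocol.

    Parameters
    ----------
    X : DataFrame
        Training feature table (radiomic features only).
    y : array-like
        Binary mid-term outcome (1 = non-CR).
    selectors, classifiers : sequence of str
        Method subsets (default: all seven each, 49 cells).
    k : int
        Outer CV folds (default five).
    paper_protocol : bool
        Reproduce the literal published step order, in which each selection
        model is fit once on the whole training cohort before the CV of the
        classifiers. The default re-selects inside each fold, which is the
        leakage-safe reading.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        selectors=METHODS,
        classifiers=METHODS,
        k: int = 5,
        seed: int = 0,
        selection_cv: int = 3,
        step: int = 1,
        paper_protocol: bool = False,
    ):
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if len(np.unique(self.y)) < 2:
            raise ValueError("y must contain both classes")
        self.selectors = tuple(selectors)
        self.classifiers = tuple(classifiers)
        self.k = k
        self.seed = seed
        self.selection_cv = selection_cv
        self.step = step
        self.paper_protocol = paper_protocol

    def fit(self, weight_source: str = "classifier") -> "CrossCombinationResults":
        X, y = self.X, self.y
        skf = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.seed)
        folds = list(skf.split(X, y))

        # per-fold standardization + per-(fold, selector) selection cache
        fold_data = []
        for tr, te in folds:
            scaler = _Standardizer.fit(X.iloc[tr])
            fold_data.append((tr, te, scaler.transform(X.iloc[tr]), scaler.transform(X.iloc[te])))

        selections: dict[tuple[int, str], list[str]] = {}
        for sel in self.selectors:
            if self.paper_protocol:
                scaler = _Standardizer.fit(X)
                chosen, _ = select_features(sel, scaler.transform(X), y,
                                            cv=self.selection_cv, seed=self.seed, step=self.step)
                for f in range(len(folds)):
                    selections[(f, sel)] = chosen
            else:
                for f, (tr, _, Xtr_s, _) in enumerate(fold_data):
                    selections[(f, sel)], _ = select_features(
                        sel, Xtr_s, y[tr], cv=self.selection_cv, seed=self.seed, step=self.step
                    )

        auc = pd.DataFrame(index=list(self.selectors), columns=list(self.classifiers), dtype=float)
        fold_aucs: dict[tuple[str, str], list[float]] = {}
        for sel in self.selectors:
            for clf_name in self.classifiers:
                cell = []
                for f, (tr, te, Xtr_s, Xte_s) in enumerate(fold_data):
                    feats = selections[(f, sel)]
                    clf = make_method(clf_name, role="classifier", seed=self.seed)
                    clf.fit(Xtr_s[feats].to_numpy(), y[tr])
                    cell.append(roc_auc_score(y[te], _decision_scores(clf, Xte_s[feats].to_numpy())))
                fold_aucs[(sel, clf_name)] = [float(a) for a in cell]
                auc.loc[sel, clf_name] = float(np.mean(cell))

        # argmax with ties broken lexicographically by the method listing order
        best_val = auc.to_numpy().max()
        elected = None
        for sel in self.selectors:
            for clf_name in self.classifiers:
                if auc.loc[sel, clf_name] >= best_val - 1e-12:
                    elected = (sel, clf_name)
                    break
            if elected:
                break

        radscore = fit_radscore(
            X, y, elected[0], elected[1], seed=self.seed,
            selection_cv=self.selection_cv, step=self.step, weight_source=weight_source,
        )
        train_scores = radscore.score(X)
        training_auc = float(roc_auc_score(y, train_scores))
        return CrossCombinationResults(
            model=self, auc_matrix=auc, fold_aucs=fold_aucs,
            elected_pair=elected, radscore=radscore, training_auc=training_auc,
        )


@dataclass
class CrossCombinationResults:
    """Results of the grid: AUC matrix, elected pair, fitted RadScore."""

    model: CrossCombination
    auc_matrix: pd.DataFrame
    fold_aucs: dict[tuple[str, str], list[float]]
    elected_pair: tuple[str, str]
    radscore: RadScoreModel
    training_auc: float

    @property
    def n_cells(self) -> int:
        return self.auc_matrix.size

    def fold_table(self) -> pd.DataFrame:
        """Long-format per-fold AUC table (figure-ready)."""
        rows = [
            {"selector": s, "classifier": c, "fold": i, "auc": a}
            for (s, c), aucs in self.fold_aucs.items()
            for i, a in enumerate(aucs)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cross-combination model election",
            "=" * 64,
            f"cells evaluated: {self.n_cells} "
            f"({len(self.model.selectors)} selectors x {len(self.model.classifiers)} classifiers), "
            f"{self.model.k}-fold CV, seed {self.model.seed}",
            "",
            "Mean held-out AUC (rows: selectors, columns: classifiers)",
            self.auc_matrix.round(3).to_string(),
            "",
            f"elected pair: {self.elected_pair[0]}-{self.elected_pair[1]} "
            f"(mean CV AUC {self.auc_matrix.loc[self.elected_pair]:.3f})",
            f"training AUC of the refit RadScore: {self.training_auc:.3f}",
            "",
            f"RadScore: {len(self.radscore.feature_names)} selected features "
            f"(weights from {self.radscore.weight_source} refit)",
        ]
        for name, w in zip(self.radscore.feature_names, self.radscore.weights):
            lines.append(f"  {name:<55s} {w:+.4f}")
        return "\n".join(lines)
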