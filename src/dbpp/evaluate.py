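"""Model evaluation machinery.

Confusion-matrix metrics, ROC AUC, stratified k-fold cross-validation, the
γ weighting sweep, external-set validation, score-distribution reports with
Mann–Whitney comparison, positive-unlabeled (spy) noise analysis, and
Shapley feature attribution.

Metric definitions
------------------
accuracy    = (TP + TN) / (TP + TN + FP + FN)
recall      = TP / (TP + FN)
specificity = TN / (TN + FP)
precision   = TP / (TP + FP)
f1          = harmonic mean of precision and recall

A metric whose denominator is zero is ``None`` (undefined), never silently 0.
AUC equals the Mann–Whitney U statistic divided by n_pos * n_neg, ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = ("accuracy", "recall", "specificity", "precision", "f1", "auc")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalMetrics:
    accuracy: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    counts: ConfusionCounts
    auc: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_metrics(counts: ConfusionCounts) -> EvalMetrics:
    """Accuracy/recall/specificity/precision/F1 from confusion counts."""
    if counts.total < 1:
        raise ValueError("confusion counts are all zero")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalMetrics(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        recall=recall,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        precision=precision,
        f1=f1,
        counts=counts,
    )


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank-based, ties counted half)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, scores))


def metrics_from_scores(scores, y_true, threshold: float = 0.5) -> EvalMetrics:
    """Full metric row (incl. AUC) from probabilities at a decision cutoff."""
    scores = np.asarray(scores, dtype=float)
    counts = counts_from_predictions(y_true, (scores >= threshold).astype(int))
    m = confusion_metrics(counts)
    m.auc = roc_auc(scores, y_true)
    return m


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    fold_metrics: List[EvalMetrics]
    fold_indices: List[np.ndarray]

    def summary(self) -> pd.DataFrame:
        """Mean ± sd table over folds (sd is the population of fold values)."""
        rows = {}
        for name in METRIC_NAMES:
            vals = [getattr(m, name) for m in self.fold_metrics]
            vals = [v for v in vals if v is not None]
            rows[name] = dict(
                mean=float(np.mean(vals)) if vals else np.nan,
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            )
        return pd.DataFrame(rows).T

    def mean(self, name: str) -> float:
        return float(self.summary().loc[name, "mean"])


#: a model builder takes (X_train, y_train) and returns an object with
#: predict_proba_matrix(X) -> probabilities of class 1
ModelBuilder = Callable[[np.ndarray, np.ndarray], object]


def kfold_cv(
    X,
    y,
    model_builder: ModelBuilder,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation of a training recipe.

    The builder is called afresh inside each fold, so every piece of
    preprocessing it contains (scalers, grid search) sees training-fold data
    only.  Folds are disjoint, cover the dataset, and are seeded.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k and k != len(y):
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    if k == len(y):  # leave-one-out: stratification degenerates to identity folds
        folds = [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
        fold_metrics = []
        loo_scores = np.empty(len(y))
        for train_idx, test_idx in folds:
            model = model_builder(X[train_idx], y[train_idx])
            loo_scores[test_idx] = model.predict_proba_matrix(X[test_idx])
        counts_ = counts_from_predictions(y, (loo_scores >= threshold).astype(int))
        m = confusion_metrics(counts_)
        m.auc = roc_auc(loo_scores, y)
        return CVResult(fold_metrics=[m], fold_indices=[f[1] for f in folds])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics, fold_indices = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = model_builder(X[train_idx], y[train_idx])
        proba = model.predict_proba_matrix(X[test_idx])
        fold_metrics.append(metrics_from_scores(proba, y[test_idx], threshold))
        fold_indices.append(test_idx)
    return CVResult(fold_metrics=fold_metrics, fold_indices=fold_indices)


# ---------------------------------------------------------------------------
# γ sweep


@dataclass
class GammaSweepResult:
    table: pd.DataFrame  # columns gamma, auc, f1, objective
    selected_gamma: float


def gamma_sweep(
    pc: np.ndarray,
    admet: np.ndarray,
    y,
    builder_factory: Callable[[float], ModelBuilder],
    grid: Sequence[float] = (0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0),
    k: int = 5,
    seed: int = 0,
) -> GammaSweepResult:
    """Sweep the profile weighting γ and pick the best by mean(AUC, F1).

    ``builder_factory(gamma)`` yields a training recipe that applies the
    γ-weighted profile construction internally (PC scaling fitted per fold).
    Ties in the objective are broken toward γ = 0.5, the most balanced
    weighting of the two blocks.
    """
    grid = list(grid)
    if not grid or any(g < 0 or g > 1 for g in grid):
        raise ValueError("gamma grid must be non-empty with values in [0, 1]")
    X = np.hstack([np.asarray(pc, float), np.asarray(admet, float)])
    rows = []
    for g in grid:
        res = kfold_cv(X, y, builder_factory(g), k=k, seed=seed)
        auc = res.mean("auc")
        f1 = res.mean("f1")
        rows.append(dict(gamma=g, auc=auc, f1=f1, objective=(auc + f1) / 2.0))
    table = pd.DataFrame(rows)
    best = table["objective"].max()
    candidates = table.loc[np.isclose(table["objective"], best), "gamma"]
    selected = float(min(candidates, key=lambda g: (abs(g - 0.5), g)))
    return GammaSweepResult(table=table, selected_gamma=selected)


# ---------------------------------------------------------------------------
# External validation & score distributions


def external_validate(model, sets: Dict[str, tuple], threshold: float = 0.5) -> pd.DataFrame:
    """Evaluate a fitted scorer on named labeled sets, with no refitting.

    ``sets`` maps a set name to ``(X, y)`` where ``X`` is whatever the
    model's ``predict_proba_matrix`` accepts (a stacked [PC | ADMET] array).
    Returns one metric row per set.
    """
    rows = []
    for name, (X, y) in sets.items():
        proba = model.predict_proba_matrix(np.asarray(X, float))
        m = metrics_from_scores(proba, y, threshold)
        rows.append({"set": name, "n": len(y), **m.as_dict()})
    return pd.DataFrame(rows).set_index("set")


@dataclass
class ScoreDistributionReport:
    per_set: pd.DataFrame          # index set name; n, mean, q25, q50, q75
    pairwise_tests: pd.DataFrame   # set_a, set_b, u_statistic, p_value
    score_vectors: Dict[str, np.ndarray]


def score_distributions(score_sets: Dict[str, np.ndarray]) -> ScoreDistributionReport:
    """Per-set score summaries plus all pairwise Mann–Whitney U tests.

    Two-sided tests; SciPy's exact method for small samples without ties,
    tie-corrected normal approximation otherwise.
    """
    if not score_sets:
        raise ValueError("need at least one score set")
    per_set = {}
    for name, scores in score_sets.items():
        s = np.asarray(scores, dtype=float)
        per_set[name] = dict(
            n=len(s),
            mean=float(s.mean()),
            q25=float(np.quantile(s, 0.25)),
            q50=float(np.quantile(s, 0.50)),
            q75=float(np.quantile(s, 0.75)),
        )
    names = list(score_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = stats.mannwhitneyu(
                score_sets[a], score_sets[b], alternative="two-sided", method="auto"
            )
            rows.append(dict(set_a=a, set_b=b, u_statistic=float(u), p_value=float(p)))
    return ScoreDistributionReport(
        per_set=pd.DataFrame(per_set).T,
        pairwise_tests=pd.DataFrame(
            rows, columns=["set_a", "set_b", "u_statistic", "p_value"]
        ),
        score_vectors={k: np.asarray(v, float) for k, v in score_sets.items()},
    )


# ---------------------------------------------------------------------------
# PU (positive-unlabeled) spy analysis


def pu_noise_analysis(
    positives: np.ndarray,
    unlabeled: np.ndarray,
    spy_fraction: float = 0.15,
    seed: int = 0,
    n_replicates: int = 5,
    spy_quantile: float = 0.05,
) -> Dict[str, float]:
    """Estimate the likely-positive fraction of an unlabeled set (spy method).

    Per replicate: hide ``spy_fraction`` of the positives among the unlabeled,
    train a positive-vs-unlabeled classifier, set the reliability threshold at
    the ``spy_quantile`` of the spies' scores, and report the fraction of the
    true unlabeled scoring above it.  Returns the mean over replicates plus
    per-replicate values.
    """
    from lightgbm import LGBMClassifier

    P = np.asarray(positives, dtype=float)
    U = np.asarray(unlabeled, dtype=float)
    if len(P) == 0 or len(U) == 0:
        raise ValueError("positives and unlabeled must be non-empty")
    if not 0 < spy_fraction < 1:
        raise ValueError("spy_fraction must be in (0, 1)")
    fractions = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        n_spies = max(1, int(round(spy_fraction * len(P))))
        spy_idx = rng.choice(len(P), size=n_spies, replace=False)
        is_spy = np.zeros(len(P), dtype=bool)
        is_spy[spy_idx] = True
        X = np.vstack([P[~is_spy], P[is_spy], U])
        y = np.concatenate(
            [np.ones((~is_spy).sum()), np.zeros(n_spies + len(U))]
        )
        clf = LGBMClassifier(
            n_estimators=100, random_state=seed + r, n_jobs=1, verbose=-1,
            deterministic=True, force_row_wise=True,
        )
        clf.fit(X, y)
        spy_scores = clf.predict_proba(P[is_spy])[:, 1]
        threshold = np.quantile(spy_scores, spy_quantile)
        u_scores = clf.predict_proba(U)[:, 1]
        fractions.append(float((u_scores > threshold).mean()))
    return {
        "likely_positive_fraction": float(np.mean(fractions)),
        "per_replicate": fractions,
        "spy_fraction": spy_fraction,
        "spy_quantile": spy_quantile,
    }


# ---------------------------------------------------------------------------
# Shapley feature attribution


@dataclass
class AttributionResult:
    contributions: np.ndarray      # (n_samples, n_features), margin scale
    base_value: float
    feature_names: tuple
    importance: pd.Series          # mean |contribution| per feature, descending

    def reconstruct_margin(self) -> np.ndarray:
        return self.contributions.sum(axis=1) + self.base_value


def endpoint_attribution(model, X, feature_names=None) -> AttributionResult:
    """Per-feature Shapley attribution of a fitted drug-likeness classifier.

    Tree models use exact tree-path (TreeSHAP) attribution computed by the
    boosting library itself; linear models use the closed form
    ``w_j * (x_j - mean_j)``.  In both cases local accuracy holds: per-sample
    attributions plus the base value reconstruct the model's margin (log-odds)
    output.
    """
    X = np.asarray(X, dtype=float)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    clf = getattr(model, "classifier", model)

    if hasattr(clf, "booster_"):  # LightGBM
        contrib = clf.predict(X, pred_contrib=True)
        base = float(contrib[0, -1])
        contributions = contrib[:, :-1]
    elif hasattr(clf, "coef_"):  # linear (logistic) model
        w = np.asarray(clf.coef_).ravel()
        mu = X.mean(axis=0)
        contributions = w[None, :] * (X - mu[None, :])
        base = float(w @ mu + float(np.asarray(clf.intercept_).ravel()[0]))
    else:
        raise TypeError(
            "attribution supports tree (LightGBM) and linear models only"
        )
    importance = pd.Series(
        np.abs(contributions).mean(axis=0), index=list(names)
    ).sort_values(ascending=False)
    return AttributionResult(
        contributions=contributions,
        base_value=base,
        feature_names=names,
        importance=importance,
    )


def point_biserial_correlations(X, y, feature_names=None) -> pd.Series:
    """Plain point-biserial correlation of each feature with the binary label.

    A simple stand-in for endpoint-vs-drug-likeness correlation ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    vals = [stats.pointbiserialr(y, X[:, j]).statistic for j in range(X.shape[1])]
    return pd.Series(vals, index=names)
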