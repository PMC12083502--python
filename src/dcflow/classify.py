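"""ImgSVM classification and the multi-metric evaluation protocol.

An RBF-kernel support vector machine is trained on z-scored image features,
with (C, gamma) grid-searched on a log2 lattice by stratified five-fold
cross-validated accuracy (ties broken toward smaller C, then smaller gamma)
and Platt-scaled probability outputs.  Evaluation covers six metrics —
accuracy, sensitivity, specificity, AUC-ROC, AUC-PR, and the
Hosmer-Lemeshow calibration p-value — averaged over repeated random
stratified train/test splits, plus the rank-sum aggregate score (per
metric, descending dense ranks scored 10, 9, ... with ties sharing a
score) and random-forest feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    precision_recall_curve,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitConfig",
    "EvalReport",
    "train_imgsvm",
    "hosmer_lemeshow",
    "evaluate",
    "aggregate_score",
    "replicate_experiment",
    "rf_importance",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "malignant"

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc_roc", "auc_pr",
                "calibration_p")

# LIBSVM-style log2 grid
C_GRID = 2.0 ** np.arange(-5, 16, 2)
GAMMA_GRID = 2.0 ** np.arange(-15, 4, 2)


@dataclass(frozen=True)
class SplitConfig:
    """Repeated stratified train/test split protocol."""

    n_train_pos: int = 11
    n_train_neg: int = 28
    n_test_pos: int = 10
    n_test_neg: int = 10
    replications: int = 20
    cv_folds: int = 5
    seed: int = 0

    @property
    def n_train(self) -> int:
        return self.n_train_pos + self.n_train_neg

    @property
    def n_test(self) -> int:
        return self.n_test_pos + self.n_test_neg


@dataclass
class EvalReport:
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    auc_ci: dict[str, tuple[float, float]]
    per_replication: pd.DataFrame
    replication_seeds: list[int]


def train_imgsvm(
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
) -> CalibratedClassifierCV:
    """Grid-searched RBF SVM with probability outputs.

    Features are z-scored by training statistics; (C, gamma) maximize mean
    stratified five-fold CV accuracy over C in 2^-5..2^15, gamma in
    2^-15..2^3 (ties toward smaller C, then smaller gamma); the winner is
    refit on the full training set with Platt-scaled probabilities.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    cv_folds = int(min(cv_folds, counts.min()))
    if cv_folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (-np.inf, None, None)
    for c in C_GRID:
        for g in GAMMA_GRID:
            accs = []
            for tr, va in folds:
                clf = Pipeline(
                    [("scale", StandardScaler()), ("svm", SVC(C=c, gamma=g, kernel="rbf"))]
                )
                clf.fit(X[tr], y[tr])
                accs.append(accuracy_score(y[va], clf.predict(X[va])))
            score = float(np.mean(accs))
            if score > best[0]:  # strict: first (smallest C, gamma) wins ties
                best = (score, c, g)
    _, c, g = best
    base = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(C=c, gamma=g, kernel="rbf"))]
    )
    # Platt-style sigmoid calibration fitted within training folds
    model = CalibratedClassifierCV(
        base,
        method="sigmoid",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    model.fit(X, y)
    model.selected_params_ = {"C": float(c), "gamma": float(g), "cv_accuracy": best[0]}
    return model


def hosmer_lemeshow(probabilities: np.ndarray, outcomes: np.ndarray,
                    n_groups: int = 10, df_reduction: int = 2) -> float:
    """Hosmer-Lemeshow goodness-of-fit p-value.

    Samples are grouped by predicted-probability deciles; the chi-square
    statistic compares observed and expected event counts per group, on
    g - ``df_reduction`` degrees of freedom (g = number of nonempty
    groups).  The default g - 2 is the convention for probabilities from a
    model fitted to the same data; for externally specified probabilities
    (validation data, simulated truth) the statistic is chi-square on g
    degrees of freedom, so pass ``df_reduction=0`` there.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    edges = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], p, side="right"), 0, n_groups - 1)
    chi2_stat = 0.0
    g = 0
    for k in range(n_groups):
        sel = idx == k
        n = sel.sum()
        if n == 0:
            continue
        g += 1
        o1 = y[sel].sum()
        e1 = p[sel].sum()
        e0 = n - e1
        # guard degenerate expected counts
        chi2_stat += (o1 - e1) ** 2 / max(e1, 1e-10)
        chi2_stat += ((n - o1) - e0) ** 2 / max(e0, 1e-10)
    df = g - df_reduction
    if df < 1:
        return float("nan")
    return float(chi2.sf(chi2_stat, df))


def evaluate(
    predictions: np.ndarray,
    probabilities: np.ndarray,
    labels: np.ndarray,
    positive=POSITIVE_LABEL,
) -> dict[str, float]:
    """Six evaluation metrics for one test set (positive = malignant).

    AUC-ROC is the trapezoidal rank statistic; AUC-PR integrates the
    precision-recall curve; calibration p comes from the Hosmer-Lemeshow
    test with 10 probability-decile groups.  Degenerate single-class labels
    leave the AUCs as NaN.
    """
    yp = np.asarray(predictions) == positive
    yt = np.asarray(labels) == positive
    prob = np.asarray(probabilities, dtype=float)
    if yp.shape != yt.shape or prob.shape != yt.shape:
        raise ValueError("predictions, probabilities and labels must align")
    tp = np.sum(yp & yt)
    tn = np.sum(~yp & ~yt)
    fp = np.sum(yp & ~yt)
    fn = np.sum(~yp & yt)
    npos, nneg = tp + fn, tn + fp
    out = {
        "accuracy": (tp + tn) / yt.size,
        "sensitivity": tp / npos if npos else float("nan"),
        "specificity": tn / nneg if nneg else float("nan"),
    }
    if npos and nneg:
        out["auc_roc"] = float(roc_auc_score(yt, prob))
        precision, recall, _ = precision_recall_curve(yt, prob)
        out["auc_pr"] = float(auc(recall, precision))
    else:
        out["auc_roc"] = float("nan")
        out["auc_pr"] = float("nan")
    out["calibration_p"] = hosmer_lemeshow(prob, yt)
    return {k: float(v) for k, v in out.items()}


def aggregate_score(metric_table: pd.DataFrame, top_score: int = 10) -> pd.Series:
    """Rank-sum aggregate score across metric columns (higher = better).

    Per metric, models are sorted descending and dense-ranked: the best
    value scores ``top_score``, each next distinct value one less, and ties
    share a score.  A model's aggregate is the sum over all metrics; with
    six metrics the maximum is 60.  Models with missing metrics are
    excluded with a warning.
    """
    if metric_table.shape[0] < 2:
        raise ValueError("need at least 2 models to rank")
    table = metric_table.copy()
    bad = table.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"models excluded for missing metrics: {list(table.index[bad])}")
        table = table[~bad]
    scores = pd.Series(0, index=table.index, dtype=int)
    for col in table.columns:
        dense = table[col].rank(method="dense", ascending=False).astype(int)
        scores += top_score + 1 - dense
    return scores


def _stratified_split(
    labels: np.ndarray, config: SplitConfig, rng: np.random.Generator,
    positive=POSITIVE_LABEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Random indices for one (train, test) split with the configured
    per-class counts."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == positive)
    neg = np.flatnonzero(labels != positive)
    need_pos = config.n_train_pos + config.n_test_pos
    need_neg = config.n_train_neg + config.n_test_neg
    if pos.size < need_pos or neg.size < need_neg:
        raise ValueError(
            f"cohort too small: need {need_pos} positive / {need_neg} negative, "
            f"have {pos.size} / {neg.size}"
        )
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    test = np.concatenate([pos[: config.n_test_pos], neg[: config.n_test_neg]])
    train = np.concatenate(
        [
            pos[config.n_test_pos : config.n_test_pos + config.n_train_pos],
            neg[config.n_test_neg : config.n_test_neg + config.n_train_neg],
        ]
    )
    return train, test


def replicate_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    config: SplitConfig | None = None,
) -> EvalReport:
    """Repeated random stratified splits: train, evaluate, average.

    Each replication uses seed ``config.seed + r`` (recorded in the report)
    for its split and SVM training, so any single replication can be rerun
    exactly.
    """
    config = config or SplitConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rows = []
    seeds = []
    for r in range(config.replications):
        rep_seed = config.seed + r
        seeds.append(rep_seed)
        rng = np.random.default_rng(rep_seed)
        train, test = _stratified_split(y, config, rng)
        model = train_imgsvm(X[train], y[train], cv_folds=config.cv_folds, seed=rep_seed)
        pos_col = list(model.classes_).index(POSITIVE_LABEL)
        prob = model.predict_proba(X[test])[:, pos_col]
        pred = model.predict(X[test])
        rows.append(evaluate(pred, prob, y[test]))
    per_rep = pd.DataFrame(rows)
    mean = per_rep.mean()
    sd = per_rep.std(ddof=1)
    ci = {}
    for name in ("auc_roc", "auc_pr"):
        half = 1.96 * sd[name] / np.sqrt(config.replications)
        ci[name] = (float(mean[name] - half), float(mean[name] + half))
    return EvalReport(
        metrics_mean={k: float(mean[k]) for k in METRIC_NAMES},
        metrics_sd={k: float(sd[k]) for k in METRIC_NAMES},
        auc_ci=ci,
        per_replication=per_rep,
        replication_seeds=seeds,
    )


def rf_importance(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
    feature_names=None,
) -> pd.Series:
    """Random-forest feature importances, normalized to sum exactly 1.

    Importance is the mean information gain (entropy criterion) attributed
    to each feature across the trees of a seeded forest.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="entropy", random_state=seed
    )
    rf.fit(np.asarray(features, dtype=float), y)
    imp = rf.feature_importances_.astype(float)
    imp = imp / imp.sum()
    return pd.Series(imp, index=feature_names if feature_names is not None else None)
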