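"""Leave-one-out cross-validated classification of the summary-model features.

Four classifier families mirror the conventional WEKA-style toolbox: Gaussian
naive Bayes, an entropy-based (C4.5-like) decision tree, a linear support
vector machine with unit complexity, and 1-nearest-neighbour.  Each athlete
is predicted by a model trained on all the others; per-classifier accuracy,
sensitivity, specificity and rank-based AUC are reported together with their
arithmetic-mean aggregate row.

The positive class defaults to the *low*-performing group (the larger one),
so sensitivity is the correct-classification rate of low performers and
specificity that of high performers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .grouping import GroupLabels

CLASSIFIERS = ("naive_bayes", "c45_tree", "linear_svm", "knn")

_DISPLAY_DECIMALS = {"accuracy_pct": 1, "sensitivity": 3, "specificity": 3, "auc": 3}


def _make_estimator(kind: str, seed: int):
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "c45_tree":
        # entropy criterion with a leaf-size floor as the pruning analogue
        return DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2, random_state=seed)
    if kind == "linear_svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown classifier kind {kind!r}")


def fit_predict(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int = 0,
) -> tuple[int, float]:
    """Train one classifier and predict a held-out point.

    Returns ``(label, score)`` where the score is a positive-class
    probability or margin usable for ROC construction.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    est = _make_estimator(kind, seed)
    # sort training rows so predictions cannot depend on presentation order
    order = np.lexsort(np.asarray(X_train, dtype=float).T[::-1])
    est.fit(np.asarray(X_train, dtype=float)[order], y_train[order])
    xt = np.asarray(x_test, dtype=float).reshape(1, -1)
    label = int(est.predict(xt)[0])
    if hasattr(est, "predict_proba"):
        score = float(est.predict_proba(xt)[0, list(est.classes_).index(1)])
    else:
        score = float(est.decision_function(xt)[0])
        if est.classes_[1] != 1:  # orient the margin toward the positive class
            score = -score
    return label, score


def loocv(
    data: pd.DataFrame,
    labels: GroupLabels,
    kind: str,
    seed: int = 0,
    positive_class: str = "low",
) -> pd.DataFrame:
    """Leave-one-out predictions for one classifier family.

    Returns a frame indexed by athlete with columns ``true``, ``predicted``
    (1 = positive class) and ``score``.  Exactly n folds; fold i trains on
    every athlete except i.  Results are invariant to row order because the
    frame is sorted by athlete id first.
    """
    if len(data) < 3:
        raise ValueError("leave-one-out needs at least 3 athletes")
    data = data.sort_index()
    lab = labels.labels.reindex(data.index)
    if lab.isna().any():
        raise ValueError("every athlete needs a group label")
    y = (lab == positive_class).astype(int).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        # LOOCV estimators need complete features: mean-fill, flagged loudly
        warnings.warn("missing values mean-filled for classification", stacklevel=2)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    rows = []
    for i in range(len(data)):
        tr = np.arange(len(data)) != i
        label, score = fit_predict(kind, X[tr], y[tr], X[i], seed=seed)
        rows.append({"athlete_id": data.index[i], "true": y[i], "predicted": label, "score": score})
    return pd.DataFrame(rows).set_index("athlete_id")


def confusion_metrics(
    predicted: np.ndarray | pd.Series,
    true: np.ndarray | pd.Series,
) -> tuple[float, float, float]:
    """(accuracy %, sensitivity, specificity); inputs coded 1 = positive class."""
    pred = np.asarray(predicted).astype(int)
    y = np.asarray(true).astype(int)
    if len(pred) != len(y):
        raise ValueError("predictions and labels must align")
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    accuracy = 100.0 * float((pred == y).mean())
    sensitivity = float((pred[pos] == 1).mean())
    specificity = float((pred[neg] == 0).mean())
    return accuracy, sensitivity, specificity


def roc_auc(scores: np.ndarray | pd.Series, true: np.ndarray | pd.Series) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true).astype(int)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    if np.ptp(s) == 0:
        warnings.warn("constant scores: AUC undefined, reporting 0.5", stacklevel=2)
        return 0.5
    ranks = rankdata(s)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ClassifierReport:
    """Per-classifier LOOCV metrics plus the aggregate row."""

    table: pd.DataFrame  # rows: classifiers + "all"; accuracy_pct, sens, spec, auc
    positive_class: str = "low"
    predictions: dict[str, pd.DataFrame] | None = None

    @property
    def aggregate(self) -> pd.Series:
        return self.table.loc["all"]

    def display(self) -> pd.DataFrame:
        return self.table.round(_DISPLAY_DECIMALS)


def aggregate_report(rows: pd.DataFrame, positive_class: str = "low") -> ClassifierReport:
    """Append the arithmetic-mean aggregate to four per-classifier rows."""
    if len(rows) != 4:
        raise ValueError("exactly four classifier rows expected")
    agg = rows.mean(axis=0)
    table = pd.concat([rows, agg.to_frame("all").T])
    table.index.name = "classifier"
    return ClassifierReport(table, positive_class=positive_class)


def evaluate_classifiers(
    data: pd.DataFrame,
    labels: GroupLabels,
    seed: int = 0,
    positive_class: str = "low",
) -> ClassifierReport:
    """LOOCV all four classifier families on the given feature columns."""
    rows = {}
    preds = {}
    for kind in CLASSIFIERS:
        res = loocv(data, labels, kind, seed=seed, positive_class=positive_class)
        acc, sens, spec = confusion_metrics(res["predicted"], res["true"])
        auc = roc_auc(res["score"], res["true"])
        rows[kind] = {"accuracy_pct": acc, "sensitivity": sens, "specificity": spec, "auc": auc}
        preds[kind] = res
    frame = pd.DataFrame(rows).T.loc[list(CLASSIFIERS)]
    report = aggregate_report(frame, positive_class=positive_class)
    report.predictions = preds
    return report
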