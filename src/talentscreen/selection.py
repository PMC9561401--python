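"""Consensus feature selection across four ranking algorithms.

Each attribute is scored on its own by a leave-one-out discrimination score
under four classifier families — Gaussian naive Bayes, an entropy decision
stump (C4.5-style), a class-midpoint margin rule (linear maximum-margin in
one dimension) and 1-nearest-neighbour.  Scores are balanced accuracy, which
keeps the 23-vs-6 group imbalance from rewarding majority-class guessing.
Attributes appearing in the top k (default 20) of all four rankings form the
very-important tier of the summary model, three rankings the important tier,
two the fairly-important tier.

The scorers are closed-form / vectorised over the whole attribute matrix so
that replicate simulations over hundreds of attributes stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FeatureTable
from .grouping import GroupLabels

METHODS = ("bayes", "tree", "margin", "neighbour")

TIERS = {4: "very_important", 3: "important", 2: "fairly_important"}

_EPS = 1e-9


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def minmax_normalize(table: FeatureTable | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Affinely map every column so min -> 0 and max -> 1.

    Constant columns map to 0 and are returned in the flagged list.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = hi - lo
    constant = list(data.columns[(span == 0) | span.isna()])
    safe = span.replace(0, np.nan)
    out = (data - lo) / safe
    out[constant] = 0.0
    return out, constant


# ---------------------------------------------------------------------------
# vectorised single-feature leave-one-out scorers
# ---------------------------------------------------------------------------
# X: (n, p) complete matrix; y: (n,) boolean, True = high performer.
# Each returns an (n, p) boolean prediction matrix (True = predicted high).


def _loo_predict_bayes(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, p = X.shape
    pred = np.empty((n, p), dtype=bool)
    sums = {c: X[y == c].sum(axis=0) for c in (False, True)}
    sqs = {c: (X[y == c] ** 2).sum(axis=0) for c in (False, True)}
    ns = {c: int((y == c).sum()) for c in (False, True)}
    var_floor = _EPS * (X.var(axis=0) + 1.0)
    for i in range(n):
        s, q, m = dict(sums), dict(sqs), dict(ns)
        c = bool(y[i])
        s[c] = s[c] - X[i]
        q[c] = q[c] - X[i] ** 2
        m[c] = m[c] - 1
        ll = {}
        for cls in (False, True):
            mu = s[cls] / m[cls]
            var = np.maximum(q[cls] / m[cls] - mu**2, var_floor)
            prior = m[cls] / (n - 1)
            ll[cls] = -0.5 * np.log(var) - (X[i] - mu) ** 2 / (2 * var) + np.log(prior)
        pred[i] = ll[True] > ll[False]
    return pred


def _loo_predict_margin(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Class-midpoint threshold rule: 1-D analogue of a linear margin classifier."""
    n, p = X.shape
    pred = np.empty((n, p), dtype=bool)
    sums = {c: X[y == c].sum(axis=0) for c in (False, True)}
    ns = {c: int((y == c).sum()) for c in (False, True)}
    for i in range(n):
        s, m = dict(sums), dict(ns)
        c = bool(y[i])
        s[c] = s[c] - X[i]
        m[c] = m[c] - 1
        mu0, mu1 = s[False] / m[False], s[True] / m[True]
        thr = (mu0 + mu1) / 2
        above = X[i] > thr
        pred[i] = np.where(mu1 >= mu0, above, ~above)
    return pred


def _loo_predict_neighbour(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """1-NN under absolute distance; distance ties resolve to the lowest row."""
    n, p = X.shape
    d = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, p)
    d[np.arange(n), np.arange(n), :] = np.inf
    nn = d.argmin(axis=1)  # (n, p)
    return y[nn]


def _entropy(p1: np.ndarray) -> np.ndarray:
    p1 = np.clip(p1, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p1 * np.log2(p1) + (1 - p1) * np.log2(1 - p1))
    return np.nan_to_num(h)


def _loo_predict_tree(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Depth-1 entropy stump refit on every training fold."""
    n, p = X.shape
    pred = np.empty((n, p), dtype=bool)
    rows = np.arange(n)
    for i in range(n):
        tr = rows != i
        Xt, yt = X[tr], y[tr]
        m = n - 1
        order = np.argsort(Xt, axis=0, kind="stable")
        xs = np.take_along_axis(Xt, order, axis=0)
        ys = yt[order]  # (m, p)
        tot1 = ys.sum(axis=0)
        cum1 = np.cumsum(ys, axis=0)[:-1]  # class-1 count left of each split
        nl = np.arange(1, m)[:, None].astype(float)
        nr = m - nl
        gain = _entropy(tot1 / m) - (nl * _entropy(cum1 / nl) + nr * _entropy((tot1 - cum1) / nr)) / m
        gain = np.where(xs[1:] > xs[:-1], gain, -np.inf)  # splits need distinct values
        best = gain.argmax(axis=0)
        has_split = gain[best, np.arange(p)] > 0
        thr = (xs[best, np.arange(p)] + xs[best + 1, np.arange(p)]) / 2
        nl_b = (best + 1).astype(float)
        left1 = cum1[best, np.arange(p)]
        left_high = 2 * left1 > nl_b
        right_high = 2 * (tot1 - left1) > (m - nl_b)
        majority = 2 * tot1 > m
        pick = np.where(X[i] > thr, right_high, left_high)
        pred[i] = np.where(has_split, pick, majority)
    return pred


_SCORERS = {
    "bayes": _loo_predict_bayes,
    "tree": _loo_predict_tree,
    "margin": _loo_predict_margin,
    "neighbour": _loo_predict_neighbour,
}


def _balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    sens = pred[y].mean(axis=0)
    spec = (~pred[~y]).mean(axis=0)
    return (sens + spec) / 2


@dataclass
class FeatureRanking:
    """Ordered attribute list with scores for one ranking method."""

    method: str
    attributes: list[str]  # top-k, best first
    scores: pd.Series = field(repr=False)  # all attributes

    def __post_init__(self) -> None:
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("duplicate attributes in ranking")


def rank_features(
    table: FeatureTable | pd.DataFrame,
    labels: GroupLabels,
    method: str,
    k: int = 20,
    seed: int = 0,
) -> FeatureRanking:
    """Score every attribute by single-feature LOO discrimination and rank.

    Ties break by attribute name so rankings are deterministic.  ``seed`` is
    accepted for interface symmetry; the scorers are closed-form and draw no
    randomness.
    """
    if method not in _SCORERS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    data = table.data if isinstance(table, FeatureTable) else table
    y_all = (labels.labels.reindex(data.index) == "high").to_numpy()
    if y_all.all() or not y_all.any():
        warnings.warn("labels contain a single class; ranking is degenerate", stacklevel=2)
        scores = pd.Series(0.0, index=data.columns)
    else:
        scorer = _SCORERS[method]
        scores = pd.Series(index=data.columns, dtype=float)
        complete = data.columns[data.notna().all(axis=0)]
        if len(complete):
            X = data[complete].to_numpy(dtype=float)
            scores[complete] = _balanced_accuracy(scorer(X, y_all), y_all)
        for col in data.columns.difference(complete):  # pairwise deletion
            ok = data[col].notna().to_numpy()
            if ok.sum() < 3 or y_all[ok].all() or not y_all[ok].any():
                scores[col] = 0.0
                continue
            Xc = data.loc[ok, [col]].to_numpy(dtype=float)
            scores[col] = _balanced_accuracy(scorer(Xc, y_all[ok]), y_all[ok])[0]
    if k > len(scores):
        warnings.warn(f"k={k} exceeds attribute count {len(scores)}; truncating", stacklevel=2)
        k = len(scores)
    order = sorted(scores.index, key=lambda name: (-scores[name], name))
    return FeatureRanking(method, order[:k], scores)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


@dataclass
class SummaryModel:
    """Consensus feature set tiered by cross-algorithm agreement."""

    table: pd.DataFrame  # index attribute; columns tier, n_rankings, directions

    @property
    def attributes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def consensus_model(rankings: list[FeatureRanking], k: int = 20) -> SummaryModel:
    """Intersect four top-k lists into the tiered summary model."""
    if len(rankings) != 4:
        raise ValueError("exactly four rankings required")
    top = {r.method: set(r.attributes[:k]) for r in rankings}
    if len(top) != 4:
        raise ValueError("rankings must come from four distinct methods")
    counts: dict[str, int] = {}
    for members in top.values():
        for name in members:
            counts[name] = counts.get(name, 0) + 1
    rows = [
        {"attribute": name, "tier": TIERS[c], "n_rankings": c}
        for name, c in counts.items()
        if c >= 2
    ]
    frame = pd.DataFrame(rows, columns=["attribute", "tier", "n_rankings"])
    if len(frame):
        frame = frame.sort_values(["n_rankings", "attribute"], ascending=[False, True]).set_index("attribute")
    else:
        frame = frame.set_index("attribute")
    return SummaryModel(frame)


def direction_of_influence(
    attribute: str,
    table: FeatureTable | pd.DataFrame,
    labels: GroupLabels,
) -> tuple[str, str]:
    """('+' or '-' or '0') per (low, high) group by the greater group mean."""
    data = table.data if isinstance(table, FeatureTable) else table
    col = data[attribute]
    lab = labels.labels.reindex(col.index)
    mean_high = col[lab == "high"].mean()
    mean_low = col[lab == "low"].mean()
    if mean_high > mean_low:
        return "-", "+"
    if mean_low > mean_high:
        return "+", "-"
    return "0", "0"


def annotate_directions(model: SummaryModel, table, labels: GroupLabels) -> SummaryModel:
    """Attach direction-of-influence columns to a summary model."""
    lows, highs = [], []
    for name in model.table.index:
        d_low, d_high = direction_of_influence(name, table, labels)
        lows.append(d_low)
        highs.append(d_high)
    annotated = model.table.copy()
    annotated["direction_low"] = lows
    annotated["direction_high"] = highs
    return SummaryModel(annotated)
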