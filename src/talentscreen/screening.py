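"""Logical-attribute screening with small-sample-adjusted odds ratios.

The screen turns every continuous developmental attribute into a family of
*logical attributes* ("value above threshold") over a 100-point grid spanning
the observed range, picks the lowest significant threshold by Fisher exact
inference, and summarises the winning rule by

* the small-sample-adjusted odds ratio ``a*d / ((b+1)*(c+1))`` — finite for
  every table, including zero cells;
* the Fisher exact p-value and the exact conditional confidence interval;
* the true positive rate, i.e. the rule's prevalence among high performers;
* an importance grade (High / Moderate / Low) from the midway point between
  the odds-ratio-size scale and the TPR scale.

Rules prevalent (>= ~60%) in *both* groups without discriminating them are
flagged as commonalities — baseline conditions of participation rather than
markers of high performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cohort import FeatureTable
from .grouping import GroupLabels

N_GRID = 100
#: relative slack when collecting tables "at most as probable as observed"
_TWO_SIDED_GAMMA = 1e-7

Alternative = Literal["two-sided", "greater", "less"]


# ---------------------------------------------------------------------------
# contingency counts and the small-method odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 cell counts of a logical attribute against performance group.

    ``a``: exposed & high, ``b``: exposed & low, ``c``: unexposed & high,
    ``d``: unexposed & low.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_high(self) -> int:
        return self.a + self.c

    @property
    def n_low(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def odds_ratio_small(counts: ContingencyCounts) -> float:
    """Small-sample-adjusted odds ratio ``a*d / ((b+1)*(c+1))``.

    The +1 adjustment in the off-diagonal cells keeps the estimate finite
    for zero cells: a zero numerator cell gives OR 0, a zero denominator
    cell no longer divides by zero.
    """
    return (counts.a * counts.d) / ((counts.b + 1) * (counts.c + 1))


def true_positive_rate(counts: ContingencyCounts) -> float:
    """Prevalence of the rule among high performers, ``a / (a + c)``."""
    if counts.n_high == 0:
        raise ValueError("empty high-performance group")
    return counts.a / counts.n_high


# ---------------------------------------------------------------------------
# Fisher exact inference
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _pmf_for_margin(n_high: int, n_low: int, m: int) -> tuple[np.ndarray, int]:
    """Hypergeometric pmf of cell ``a`` given margins; returns (pmf, k_min).

    Conditional on both margins, ``a ~ Hypergeom(N, n_high, m)`` where ``m``
    is the number of exposed athletes.
    """
    n = n_high + n_low
    k_min = max(0, m - n_low)
    k_max = min(n_high, m)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n, n_high, m)
    return pmf, k_min


def fisher_exact(counts: ContingencyCounts, alternative: Alternative = "two-sided") -> float:
    """Fisher exact p-value for a 2x2 table.

    Two-sided: the sum of probabilities of all fixed-margin tables at most
    as probable as the observed one (the classical minimum-likelihood rule).
    One-sided ``greater`` tests enrichment of exposure among high performers;
    ``less`` tests the protective direction.
    """
    pmf, k_min = _pmf_for_margin(counts.n_high, counts.n_low, counts.a + counts.b)
    i = counts.a - k_min
    if alternative == "greater":
        p = pmf[i:].sum()
    elif alternative == "less":
        p = pmf[: i + 1].sum()
    elif alternative == "two-sided":
        p = pmf[pmf <= pmf[i] * (1 + _TWO_SIDED_GAMMA)].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def _fisher_grid(a: np.ndarray, b: np.ndarray, n_high: int, n_low: int) -> dict[str, np.ndarray]:
    """Vectorised Fisher p-values for many tables sharing group sizes.

    Returns arrays of two-sided, greater and less p-values for tables
    ``(a_i, b_i, n_high - a_i, n_low - b_i)``.  Cheap because the pmf per
    exposed-margin is cached.
    """
    out = {k: np.empty(a.shape, dtype=float) for k in ("two-sided", "greater", "less")}
    for i, (ai, bi) in enumerate(zip(a.astype(int), b.astype(int))):
        pmf, k_min = _pmf_for_margin(n_high, n_low, ai + bi)
        j = ai - k_min
        out["greater"][i] = min(pmf[j:].sum(), 1.0)
        out["less"][i] = min(pmf[: j + 1].sum(), 1.0)
        out["two-sided"][i] = min(pmf[pmf <= pmf[j] * (1 + _TWO_SIDED_GAMMA)].sum(), 1.0)
    return out


_CI_INFINITY = np.inf  # open upper endpoints are reported as +inf


def fisher_ci(counts: ContingencyCounts, level: float = 0.95) -> tuple[float, float]:
    """Exact conditional (tail-inversion) confidence interval for the OR.

    Zero cells yield 0 / +inf endpoints.  Note the interval brackets the
    conditional maximum-likelihood odds ratio, not the small-adjusted point
    estimate, whose +1 correction matches no standard interval recipe.
    """
    res = _scipy_odds_ratio(counts.as_table(), kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return float(ci.low), float(ci.high) if np.isfinite(ci.high) else _CI_INFINITY


# ---------------------------------------------------------------------------
# threshold grid and binarisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """100 equally spaced candidate thresholds spanning an attribute's range."""

    attribute: str
    thresholds: np.ndarray
    degenerate: bool = False  # constant attribute: all thresholds equal

    def __len__(self) -> int:
        return len(self.thresholds)


def parameter_vector(values: Sequence[float] | pd.Series, attribute: str = "", n: int = N_GRID) -> ParameterVector:
    """Equally spaced thresholds from the observed minimum to maximum."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError(f"attribute {attribute!r} is fully missing")
    if x.size < 2:
        raise ValueError(f"attribute {attribute!r} needs >= 2 non-missing values")
    lo, hi = float(x.min()), float(x.max())
    return ParameterVector(attribute, np.linspace(lo, hi, n), degenerate=lo == hi)


@dataclass
class LogicalAttribute:
    """A binarised attribute: 1 when the value lies strictly above theta."""

    attribute: str
    threshold: float
    indicator: pd.Series  # 1.0 / 0.0 / NaN

    @property
    def n_exposed(self) -> int:
        return int(np.nansum(self.indicator.to_numpy()))


def binarize(values: pd.Series, theta: float, attribute: str = "", ties: str = "zero") -> LogicalAttribute:
    """Indicator of value above theta; ties code as 0 by default.

    The source idiom assigns 1 "above" and 0 "below" and is silent on
    equality; ``ties='one'`` flips that convention.
    """
    if not np.isfinite(theta):
        raise ValueError("threshold must be finite")
    x = pd.Series(values).astype(float)
    if ties == "zero":
        ind = (x > theta).astype(float)
    elif ties == "one":
        ind = (x >= theta).astype(float)
    else:
        raise ValueError("ties must be 'zero' or 'one'")
    ind[x.isna()] = np.nan
    return LogicalAttribute(attribute or getattr(values, "name", "") or "", float(theta), ind)


def contingency(logical: LogicalAttribute, labels: GroupLabels) -> tuple[ContingencyCounts, int]:
    """Cross-tabulate a logical attribute against group labels.

    Athletes with a missing indicator are excluded pairwise; the exclusion
    tally is returned alongside the counts.
    """
    ind = logical.indicator
    lab = labels.labels.reindex(ind.index)
    if lab.isna().any():
        raise ValueError(f"athletes without labels: {list(ind.index[lab.isna()])[:5]}")
    ok = ind.notna()
    n_excluded = int((~ok).sum())
    high = (lab == "high") & ok
    low = (lab == "low") & ok
    if high.sum() == 0 or low.sum() == 0:
        raise ValueError("a group is empty after missing-value exclusions")
    a = int(ind[high].sum())
    b = int(ind[low].sum())
    counts = ContingencyCounts(a, b, int(high.sum()) - a, int(low.sum()) - b)
    return counts, n_excluded


# ---------------------------------------------------------------------------
# threshold optimisation
# ---------------------------------------------------------------------------

BRANCH_BOTH = "both_directions"
BRANCH_SINGLE = "single_direction"
BRANCH_FALLBACK = "range_minimum"
BRANCH_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class OptimizedThreshold:
    attribute: str
    theta: float
    branch: str
    index: int  # position within the parameter vector
    #: directional p-values at the selected threshold: enrichment of the
    #: rule among high performers, and the protective direction
    p_enrich: float = np.nan
    p_protect: float = np.nan

    @property
    def p_selection(self) -> float:
        """The p-value that drove (or failed) the selection cascade."""
        return float(np.nanmin([self.p_enrich, self.p_protect]))

    @property
    def significant(self) -> bool:
        return self.branch in (BRANCH_BOTH, BRANCH_SINGLE)


def optimize_parameter(
    values: pd.Series,
    labels: GroupLabels,
    vector: ParameterVector | None = None,
    alpha: float = 0.05,
    mode: str = "directional",
    ties: str = "zero",
) -> OptimizedThreshold:
    """Pick the optimised threshold for one attribute.

    Selection cascade over the ascending 100-point grid:

    1. lowest theta significant in both directional samples — enrichment of
       the rule among high performers and its depletion among low performers
       (one-sided Fisher tests, both required below ``alpha``);
    2. else the lowest theta with at least one directional p below ``alpha``
       (here the protective direction also counts, which is how
       below-one-odds-ratio rules become selectable);
    3. else the minimum of the range.

    ``mode='literal'`` replaces both directional tests with the two-sided
    p-value, collapsing branches 1 and 2.
    """
    name = getattr(values, "name", "") or ""
    if vector is None:
        vector = parameter_vector(values, name)
    if vector.degenerate:
        return OptimizedThreshold(name, float(vector.thresholds[0]), BRANCH_DEGENERATE, 0)

    x = pd.Series(values).astype(float)
    lab = labels.labels.reindex(x.index)
    ok = x.notna()
    high = ((lab == "high") & ok).to_numpy()
    low = ((lab == "low") & ok).to_numpy()
    n_high, n_low = int(high.sum()), int(low.sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must contain non-missing values")

    xv = x.to_numpy(dtype=float)
    grid = vector.thresholds
    above = np.greater if ties == "zero" else np.greater_equal
    ind = above(xv[:, None], grid[None, :])  # athletes x thresholds
    a = ind[high].sum(axis=0)
    b = ind[low].sum(axis=0)
    p = _fisher_grid(a, b, n_high, n_low)

    if mode == "literal":
        enrich = protect = p["two-sided"]
        directional = p["two-sided"]
    elif mode == "directional":
        # conditional on the margins the two group perspectives coincide,
        # so "both samples" reduces to the enrichment p; the protective
        # direction enters at branch 2
        enrich = p["greater"]
        protect = p["less"]
        directional = np.minimum(enrich, protect)
    else:
        raise ValueError("mode must be 'directional' or 'literal'")

    both = enrich < alpha
    if both.any():
        i = int(np.argmax(both))
        return OptimizedThreshold(name, float(grid[i]), BRANCH_BOTH, i, float(enrich[i]), float(protect[i]))
    single = directional < alpha
    if single.any():
        i = int(np.argmax(single))
        return OptimizedThreshold(name, float(grid[i]), BRANCH_SINGLE, i, float(enrich[i]), float(protect[i]))
    return OptimizedThreshold(name, float(grid[0]), BRANCH_FALLBACK, 0, float(enrich[0]), float(protect[0]))


# ---------------------------------------------------------------------------
# importance grading
# ---------------------------------------------------------------------------

NOT_SIGNIFICANT = "not_significant"
IMPORTANCE_LEVELS = (NOT_SIGNIFICANT, "low", "moderate", "high")


@dataclass(frozen=True)
class ImportanceScales:
    """Calibration of the two 0-100 scales combined into the importance grade.

    The odds-ratio scale is piecewise linear through ``or_anchors`` ->
    ``anchor_scores`` (clipped outside); the TPR scale likewise through
    ``tpr_anchors``.  A significant rule's grade is the midpoint of its two
    scale positions mapped through ``high_cut`` / ``moderate_cut``.  The
    defaults are calibrated so that an odds ratio above 4.6 combined with a
    TPR above 60% always grades High.
    """

    or_anchors: tuple[float, ...] = (4.6, 17.0, 23.0, 31.0)
    tpr_anchors: tuple[float, ...] = (0.0, 0.30, 0.60, 1.0)
    anchor_scores: tuple[float, ...] = (0.0, 33.0, 66.0, 100.0)
    high_cut: float = 33.0
    moderate_cut: float = 15.0

    def __post_init__(self) -> None:
        for seq in (self.or_anchors, self.tpr_anchors, self.anchor_scores):
            if not all(s < t for s, t in zip(seq, seq[1:])):
                raise ValueError("scale anchors must be strictly increasing")
        if not self.moderate_cut < self.high_cut:
            raise ValueError("grade cut-offs must be strictly increasing")

    @classmethod
    def from_distribution(cls, significant_ors: Sequence[float], **kwargs) -> "ImportanceScales":
        """Anchor the OR scale at the 0th/33rd/66th/100th percentiles of a
        run's significant odds ratios (magnitudes; protective ORs inverted)."""
        ors = np.asarray(significant_ors, dtype=float)
        if ors.size == 0:
            raise ValueError("empty odds-ratio distribution")
        mags = np.where(ors >= 1, ors, np.divide(1.0, ors, out=np.full_like(ors, np.inf), where=ors > 0))
        mags = mags[np.isfinite(mags)]
        anchors = tuple(np.percentile(mags, [0, 33, 66, 100]))
        if not all(s < t for s, t in zip(anchors, anchors[1:])):
            raise ValueError("degenerate odds-ratio distribution")
        return cls(or_anchors=anchors, **kwargs)

    def or_score(self, or_value: float) -> float:
        return float(np.interp(or_value, self.or_anchors, self.anchor_scores))

    def tpr_score(self, tpr: float) -> float:
        return float(np.interp(tpr, self.tpr_anchors, self.anchor_scores))


def grade_importance(
    or_small: float,
    tpr: float,
    significant: bool,
    scales: ImportanceScales | None = None,
    low_rate: float | None = None,
) -> str:
    """High / Moderate / Low grade for a significant logical attribute.

    Risk-direction rules (OR >= 1) are positioned by the odds ratio and the
    TPR.  Protective rules (OR < 1) indicate the *low* group, so when the
    low-group prevalence is supplied they are positioned by the magnitude
    1/OR and that prevalence; without it the risk-direction scale applies
    and small ORs grade low.
    """
    if not significant:
        return NOT_SIGNIFICANT
    scales = scales or ImportanceScales()
    if or_small < 1 and low_rate is not None:
        magnitude = np.inf if or_small == 0 else 1.0 / or_small
        midpoint = (scales.or_score(magnitude) + scales.tpr_score(low_rate)) / 2
    else:
        midpoint = (scales.or_score(or_small) + scales.tpr_score(tpr)) / 2
    if midpoint >= scales.high_cut:
        return "high"
    if midpoint >= scales.moderate_cut:
        return "moderate"
    return "low"


def find_commonalities(
    screen: pd.DataFrame,
    prevalence_threshold: float = 0.60,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag non-discriminating rules prevalent in both groups.

    A rule whose within-group prevalence reaches ``prevalence_threshold`` in
    *both* groups while its Fisher p is not below ``alpha`` is a candidate
    baseline requirement for participation.  Judging its theoretical
    relevance is left to the analyst: the returned frame is a reviewer
    checklist, not a verdict.
    """
    prev_high = screen["tpr"]
    prev_low = screen["low_rate"]
    if "significant" in screen.columns:
        non_discriminating = ~screen["significant"].astype(bool)
    else:
        non_discriminating = screen["p_value"] >= alpha
    flag = non_discriminating & (prev_high >= prevalence_threshold) & (prev_low >= prevalence_threshold)
    out = screen.loc[flag, ["theta", "tpr", "low_rate", "p_value"]].copy()
    out["review_theoretical_relevance"] = True
    return out


# ---------------------------------------------------------------------------
# whole-cohort screen
# ---------------------------------------------------------------------------


def screen_attributes(
    table: FeatureTable | pd.DataFrame,
    labels: GroupLabels,
    alpha: float = 0.05,
    scales: ImportanceScales | None = None,
    mode: str = "directional",
    ties: str = "zero",
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Run the full screen: optimise, test and grade every attribute.

    Returns one row per attribute with the optimised threshold, the branch
    of the selection cascade that fired, the 2x2 cells, the small-adjusted
    odds ratio, Fisher p, exact CI, TPR, importance grade and commonality
    candidacy.  Deterministic for fixed data.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    scales = scales or ImportanceScales()
    rows = []
    for name in data.columns:
        col = data[name]
        if col.notna().sum() < 2 or labels.labels.reindex(col.index)[col.notna()].nunique() < 2:
            continue
        vector = parameter_vector(col, name)
        opt = optimize_parameter(col, labels, vector, alpha=alpha, mode=mode, ties=ties)
        logical = binarize(col, opt.theta, name, ties=ties)
        counts, n_excluded = contingency(logical, labels)
        or_s = odds_ratio_small(counts)
        p = fisher_exact(counts, "two-sided")
        ci = fisher_ci(counts) if compute_ci else (np.nan, np.nan)
        tpr = true_positive_rate(counts)
        low_rate = counts.b / counts.n_low
        # the discriminator verdict uses the same directional p-values that
        # drove threshold selection; the two-sided p is reported alongside
        sig = opt.significant
        rows.append(
            {
                "attribute": name,
                "theta": opt.theta,
                "branch": opt.branch,
                "a": counts.a,
                "b": counts.b,
                "c": counts.c,
                "d": counts.d,
                "n_excluded": n_excluded,
                "or_small": or_s,
                "p_value": p,
                "p_selection": opt.p_selection,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "tpr": tpr,
                "low_rate": low_rate,
                "significant": sig,
                "importance": grade_importance(or_s, tpr, sig, scales, low_rate=low_rate),
            }
        )
    out = pd.DataFrame(rows).set_index("attribute")
    out["commonality"] = False
    if len(out):
        out.loc[find_commonalities(out, alpha=alpha).index, "commonality"] = True
    return out
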