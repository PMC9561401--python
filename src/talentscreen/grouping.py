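"""Performance grouping: percentile standing against a normative reference.

An athlete is labelled *high* performing when their best competition total
reaches the 80th percentile (configurable) of the reference population for
their age group, sex and bodyweight class; everyone else is *low*.  The
percentile is the weak empirical one: 100 * #(reference <= total) / n, so
ties count and the stratum maximum sits at 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NormsTable, validate_records

HIGH, LOW = "high", "low"


@dataclass
class GroupLabels:
    """Per-athlete high/low label plus the decision context."""

    labels: pd.Series  # athlete id -> "high" / "low"
    threshold: float
    #: best (or latest) total-percentile per athlete that drove the decision
    percentiles: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    statistic: str = "best"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 100:
            raise ValueError("percentile threshold must lie in (0, 100)")
        bad = set(self.labels.unique()) - {HIGH, LOW}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())

    def is_high(self) -> pd.Series:
        return self.labels == HIGH

    @classmethod
    def from_series(cls, labels: pd.Series, threshold: float = 80.0) -> "GroupLabels":
        return cls(labels=labels, threshold=threshold)

    def write(self, path) -> None:
        out = pd.DataFrame({"label": self.labels})
        if len(self.percentiles):
            out["percentile"] = self.percentiles
        out.index.name = "athlete_id"
        out.to_csv(path)


def performance_percentile(total: float, stratum: tuple, reference: NormsTable) -> float:
    """Empirical percentile of a total within its performance stratum."""
    sample = reference.reference_sample(stratum)
    return 100.0 * float(np.count_nonzero(sample <= total)) / sample.size


def assign_performance_groups(
    records: pd.DataFrame,
    reference: NormsTable,
    threshold: float = 80.0,
    statistic: str = "best",
) -> GroupLabels:
    """Label each athlete high/low from their competition records.

    Parameters
    ----------
    records
        One row per athlete-competition (see :data:`cohort.RECORD_COLUMNS`).
    reference
        Normative reference with performance strata keyed by
        (age_group, sex, bodyweight_class).
    threshold
        "Top 80th percentile" is read as percentile >= threshold.
    statistic
        ``best`` (default) uses the athlete's best total-percentile over the
        window; ``latest`` uses the chronologically last record.
    """
    if statistic not in ("best", "latest"):
        raise ValueError("statistic must be 'best' or 'latest'")
    rec = validate_records(records)
    rec = rec[rec["total_kg"].notna()]
    if rec.empty:
        raise ValueError("no usable competition records")

    per_athlete: dict = {}
    for athlete, grp in rec.groupby("athlete_id", sort=True):
        pcts = [
            performance_percentile(row["total_kg"], (row["age_group"], row["sex"], row["bodyweight_class"]), reference)
            for _, row in grp.iterrows()
        ]
        if statistic == "best":
            per_athlete[athlete] = max(pcts)
        else:
            order = np.argsort(grp["date"].to_numpy(), kind="stable")
            per_athlete[athlete] = pcts[order[-1]]

    pct = pd.Series(per_athlete).sort_index()
    labels = pd.Series(np.where(pct >= threshold, HIGH, LOW), index=pct.index)
    return GroupLabels(labels=labels, threshold=threshold, percentiles=pct, statistic=statistic)


def check_coverage(records: pd.DataFrame, athletes) -> None:
    """Raise listing athletes without any competition record."""
    have = set(records["athlete_id"].unique())
    missing = [a for a in athletes if a not in have]
    if missing:
        raise ValueError(f"athletes without competition records: {missing}")
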