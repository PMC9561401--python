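"""Cohort data model: feature tables, codebooks, performance records and norms.

A cohort is a rectangular athlete x attribute table.  Every attribute carries
codebook metadata: the developmental *theme* it belongs to (demographics,
physiology, psychosocial profile, sport history, or the microstructure of
weightlifting practice) and a *dtype* that drives validation and synthetic
generation.  Anthropometric attributes are typically expressed as deviations
from an age/sex norm ("above norm" in reporting), which is what
:func:`norm_deviation` computes.

Missing cells are kept as NaN and never imputed; downstream screens use
pairwise deletion per attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

THEMES = (
    "demographics",
    "physiology",
    "psychosocial",
    "sport_history",
    "practice_microstructure",
)

DTYPES = (
    "continuous",
    "likert_1_7",
    "hours_per_week",
    "proportion_0_1",
    "binary",
    "count",
)

#: canonical missing marker used in delimited files
MISSING_MARKER = "NA"


@dataclass(frozen=True)
class AttributeMeta:
    """Codebook entry for one developmental attribute."""

    name: str
    theme: str
    dtype: str
    norm_adjusted: bool = False
    #: ordering key for chronological (radar) presentation; lower = earlier
    order: int = 0

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise ValueError(f"unknown theme {self.theme!r} for attribute {self.name!r}")
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for attribute {self.name!r}")

    def validate_values(self, values: pd.Series) -> list[str]:
        """Return a list of human-readable violations for non-missing values."""
        x = values.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        v = x[ok]
        if self.dtype == "likert_1_7":
            bad = (v < 1) | (v > 7)
        elif self.dtype == "proportion_0_1":
            bad = (v < 0) | (v > 1)
        elif self.dtype == "hours_per_week":
            bad = v < 0
        elif self.dtype == "binary":
            bad = (v != 0) & (v != 1)
        elif self.dtype == "count":
            bad = (v < 0) | (v != np.floor(v))
        else:  # continuous: anything finite goes
            bad = ~np.isfinite(v)
        if not bad.any():
            return []
        idx = values.index[ok][bad]
        return [
            f"attribute {self.name!r}, athlete {i!r}: value {val!r} violates dtype {self.dtype}"
            for i, val in zip(idx, v[bad])
        ]


class Codebook(Mapping[str, AttributeMeta]):
    """Mapping of attribute name -> :class:`AttributeMeta`."""

    def __init__(self, entries: Iterable[AttributeMeta]):
        self._entries: dict[str, AttributeMeta] = {}
        for e in entries:
            if e.name in self._entries:
                raise ValueError(f"duplicate codebook entry {e.name!r}")
            self._entries[e.name] = e

    def __getitem__(self, key: str) -> AttributeMeta:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": list(self._entries),
                "theme": [e.theme for e in self._entries.values()],
                "dtype": [e.dtype for e in self._entries.values()],
                "norm_adjusted": [e.norm_adjusted for e in self._entries.values()],
                "order": [e.order for e in self._entries.values()],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Codebook":
        return cls(
            AttributeMeta(
                name=str(r["name"]),
                theme=str(r["theme"]),
                dtype=str(r["dtype"]),
                norm_adjusted=bool(r.get("norm_adjusted", False)),
                order=int(r.get("order", 0)),
            )
            for _, r in frame.iterrows()
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "Codebook":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class FeatureTable:
    """Athletes x attributes with codebook metadata; missing cells are NaN."""

    data: pd.DataFrame
    codebook: Codebook
    #: validation messages collected at construction (row/column coordinates)
    violations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("athlete ids must be unique")
        missing_meta = [c for c in self.data.columns if c not in self.codebook]
        if missing_meta:
            raise KeyError(f"columns without codebook entry: {missing_meta[:5]}")
        self.violations = []
        for col in self.data.columns:
            self.violations.extend(self.codebook[col].validate_values(self.data[col]))

    @property
    def athletes(self) -> pd.Index:
        return self.data.index

    @property
    def n_athletes(self) -> int:
        return len(self.data.index)

    @property
    def n_attributes(self) -> int:
        return self.data.shape[1]

    def column(self, name: str) -> pd.Series:
        return self.data[name]


def read_cohort(table_path: str | Path, codebook_path: str | Path) -> FeatureTable:
    """Read a delimited athlete x attribute table validated against a codebook.

    Unparseable cells become missing with a warning; a column absent from the
    codebook is a hard error.
    """
    codebook = Codebook.read(codebook_path)
    raw = pd.read_csv(table_path, index_col=0, dtype=str, keep_default_na=False)
    data = {}
    for col in raw.columns:
        if col not in codebook:
            raise KeyError(f"column {col!r} has no codebook entry")
        cleaned = raw[col].replace({MISSING_MARKER: np.nan, "": np.nan})
        numeric = pd.to_numeric(cleaned, errors="coerce")
        garbled = cleaned.notna() & numeric.isna()
        for idx in cleaned.index[garbled]:
            warnings.warn(
                f"unparseable cell at athlete {idx!r}, attribute {col!r}: "
                f"{cleaned[idx]!r} recorded as missing",
                stacklevel=2,
            )
        data[col] = numeric
    frame = pd.DataFrame(data, index=raw.index)
    frame.index.name = raw.index.name or "athlete_id"
    return FeatureTable(frame, codebook)


def write_cohort(table: FeatureTable, table_path: str | Path, codebook_path: str | Path | None = None) -> None:
    """Write a cohort (and optionally its codebook) as delimited text."""
    out = table.data.copy()
    out.index.name = out.index.name or "athlete_id"
    out.to_csv(table_path, na_rep=MISSING_MARKER)
    if codebook_path is not None:
        table.codebook.write(codebook_path)


# ---------------------------------------------------------------------------
# performance records
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "athlete_id",
    "date",
    "snatch_kg",
    "clean_and_jerk_kg",
    "total_kg",
    "sex",
    "age_group",
    "bodyweight_class",
]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate competition records: positive weights, total = snatch + C&J."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"performance records missing columns: {missing}")
    rec = records.copy()
    for col in ("snatch_kg", "clean_and_jerk_kg", "total_kg"):
        if (rec[col].dropna() <= 0).any():
            raise ValueError(f"non-positive weights in column {col}")
    full = rec[["snatch_kg", "clean_and_jerk_kg", "total_kg"]].notna().all(axis=1)
    bad = full & (
        (rec.loc[full, "snatch_kg"] + rec.loc[full, "clean_and_jerk_kg"] - rec.loc[full, "total_kg"]).abs() > 1e-9
    )
    if bad.any():
        raise ValueError(f"total != snatch + clean&jerk for rows {list(rec.index[bad])[:5]}")
    return rec


def read_records(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path))


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    validate_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# norms
# ---------------------------------------------------------------------------


class NormsTable:
    """Normative reference per stratum.

    Two kinds of strata coexist:

    * anthropometric norms — a single expected value per (age_group, sex)
      stratum and measurement, used by :func:`norm_deviation`;
    * performance strata — a reference sample of competition totals per
      (age_group, sex, bodyweight_class), used for empirical percentiles.
    """

    def __init__(
        self,
        expected: Mapping[tuple, float] | None = None,
        reference_samples: Mapping[tuple, np.ndarray] | None = None,
    ):
        self.expected = dict(expected or {})
        self.reference_samples = {k: np.asarray(v, dtype=float) for k, v in (reference_samples or {}).items()}
        for key, sample in self.reference_samples.items():
            if sample.size == 0:
                raise ValueError(f"empty reference sample for stratum {key}")

    def expected_value(self, stratum: tuple) -> float:
        try:
            return self.expected[tuple(stratum)]
        except KeyError:
            raise KeyError(f"unknown anthropometric stratum {tuple(stratum)!r}") from None

    def reference_sample(self, stratum: tuple) -> np.ndarray:
        try:
            return self.reference_samples[tuple(stratum)]
        except KeyError:
            raise KeyError(f"unknown performance stratum {tuple(stratum)!r}") from None

    # delimited round-trip: long format, one row per reference value / norm
    def write(self, path: str | Path) -> None:
        rows = []
        for key, val in self.expected.items():
            rows.append({"kind": "expected", "stratum": "|".join(map(str, key)), "value": val})
        for key, sample in self.reference_samples.items():
            for v in sample:
                rows.append({"kind": "reference", "stratum": "|".join(map(str, key)), "value": v})
        pd.DataFrame(rows, columns=["kind", "stratum", "value"]).to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "NormsTable":
        frame = pd.read_csv(path)
        expected = {}
        samples: dict[tuple, list[float]] = {}
        for _, r in frame.iterrows():
            key = tuple(str(r["stratum"]).split("|"))
            if r["kind"] == "expected":
                expected[key] = float(r["value"])
            else:
                samples.setdefault(key, []).append(float(r["value"]))
        return cls(expected, {k: np.array(v) for k, v in samples.items()})


def norm_deviation(value: float, stratum: tuple, norms: NormsTable) -> float:
    """Measurement minus the expected value for its age/sex stratum.

    Downstream logical rules such as "tibia length > 3.79 cm above norm"
    operate on this deviation.
    """
    return value - norms.expected_value(stratum)
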