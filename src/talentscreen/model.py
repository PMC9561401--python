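"""Model/Results interface tying the whole analysis together.

:class:`HolisticProfileModel` holds a cohort (feature table + performance
group labels) and ``fit()`` runs the full pipeline in order:

1. logical-attribute screening — threshold optimisation, small-adjusted odds
   ratios, Fisher exact inference, importance grades, commonalities;
2. min-max normalisation and the four feature rankings;
3. the top-20 consensus summary model with directions of influence;
4. leave-one-out cross-validated classification of the model features;
5. plot-ready radar data (per-group normalised means per model feature).

The returned :class:`HolisticProfileResults` carries every stage's output,
prints a statsmodels-style ``summary()`` and can persist the whole bundle as
delimited text with the seed and a config hash embedded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import FeatureTable, NormsTable, read_cohort, read_records
from .evaluate import ClassifierReport, evaluate_classifiers
from .grouping import GroupLabels, assign_performance_groups, check_coverage
from .screening import ImportanceScales, find_commonalities, screen_attributes
from .selection import (
    FeatureRanking,
    METHODS,
    SummaryModel,
    annotate_directions,
    consensus_model,
    minmax_normalize,
    rank_features,
)


@dataclass
class FitSettings:
    alpha: float = 0.05
    percentile_threshold: float = 80.0
    top_k: int = 20
    mode: str = "directional"
    ties: str = "zero"
    positive_class: str = "low"
    seed: int = 0
    scales: ImportanceScales = field(default_factory=ImportanceScales)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "scales"}
            | {"scales": self.scales.__dict__},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class HolisticProfileModel:
    """Holistic athlete-development profile analysis for one cohort.

    Parameters
    ----------
    features
        Athlete x attribute table with codebook metadata.
    groups
        High/low performance labels.  Use :meth:`from_records` to derive them
        from competition records and a normative reference instead.
    """

    def __init__(self, features: FeatureTable, groups: GroupLabels):
        missing = groups.labels.index.symmetric_difference(features.athletes)
        if len(missing):
            raise ValueError(f"features and labels disagree on athletes: {list(missing)[:5]}")
        self.features = features
        self.groups = groups

    @classmethod
    def from_records(
        cls,
        features: FeatureTable,
        records: pd.DataFrame,
        norms: NormsTable,
        threshold: float = 80.0,
        statistic: str = "best",
    ) -> "HolisticProfileModel":
        check_coverage(records, features.athletes)
        groups = assign_performance_groups(records, norms, threshold=threshold, statistic=statistic)
        return cls(features, GroupLabels(groups.labels.reindex(features.athletes),
                                         groups.threshold,
                                         groups.percentiles.reindex(features.athletes),
                                         groups.statistic))

    @classmethod
    def from_files(
        cls,
        table_path,
        codebook_path,
        labels_path=None,
        records_path=None,
        norms_path=None,
        threshold: float = 80.0,
    ) -> "HolisticProfileModel":
        features = read_cohort(table_path, codebook_path)
        if labels_path is not None:
            lab = pd.read_csv(labels_path, index_col=0)["label"]
            return cls(features, GroupLabels.from_series(lab, threshold))
        if records_path is None or norms_path is None:
            raise ValueError("provide either a labels file or records + norms files")
        return cls.from_records(features, read_records(records_path), NormsTable.read(norms_path), threshold)

    def fit(self, settings: FitSettings | None = None, **overrides) -> "HolisticProfileResults":
        settings = settings or FitSettings(**overrides)

        screening = screen_attributes(
            self.features,
            self.groups,
            alpha=settings.alpha,
            scales=settings.scales,
            mode=settings.mode,
            ties=settings.ties,
        )
        commonalities = find_commonalities(screening, alpha=settings.alpha)

        normalized, constant = minmax_normalize(self.features)
        rankings = [
            rank_features(normalized, self.groups, method, k=settings.top_k, seed=settings.seed)
            for method in METHODS
        ]
        model = consensus_model(rankings, k=settings.top_k)
        model = annotate_directions(model, normalized, self.groups)

        if len(model):
            report = evaluate_classifiers(
                normalized[model.attributes],
                self.groups,
                seed=settings.seed,
                positive_class=settings.positive_class,
            )
        else:
            report = None

        radar = export_radar_data(model, normalized, self.groups, self.features) if len(model) else pd.DataFrame()

        return HolisticProfileResults(
            model=self,
            settings=settings,
            screening=screening,
            commonalities=commonalities,
            rankings=rankings,
            summary_model=model,
            classifier_report=report,
            radar=radar,
            constant_attributes=constant,
        )


def export_radar_data(
    model: SummaryModel,
    normalized: pd.DataFrame,
    groups: GroupLabels,
    features: FeatureTable | None = None,
) -> pd.DataFrame:
    """Per-group normalised means for every summary-model feature.

    Rows are ordered chronologically via the codebook ordering key when a
    feature table is supplied, mirroring a clockwise radar layout.
    """
    missing = [a for a in model.attributes if a not in normalized.columns]
    if missing:
        raise KeyError(f"model features absent from table: {missing}")
    lab = groups.labels.reindex(normalized.index)
    rows = []
    for name in model.attributes:
        col = normalized[name]
        rows.append(
            {
                "attribute": name,
                "order": features.codebook[name].order if features is not None else 0,
                "mean_low": float(col[lab == "low"].mean()),
                "mean_high": float(col[lab == "high"].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values(["order", "attribute"]).set_index("attribute")


@dataclass
class HolisticProfileResults:
    """Everything ``fit()`` produced, with summary and persistence."""

    model: HolisticProfileModel
    settings: FitSettings
    screening: pd.DataFrame
    commonalities: pd.DataFrame
    rankings: list[FeatureRanking]
    summary_model: SummaryModel
    classifier_report: ClassifierReport | None
    radar: pd.DataFrame
    constant_attributes: list[str]

    @property
    def discriminators(self) -> pd.DataFrame:
        """Significant logical attributes, the analogue of a published
        discriminator table (rule, group prevalences, OR with CI, grade)."""
        sig = self.screening[self.screening["significant"]].copy()
        return sig.sort_values("or_small", ascending=False)

    def summary(self) -> str:
        scr = self.screening
        lines = [
            "Holistic athlete-development profile analysis",
            "=" * 60,
            f"athletes: {self.model.features.n_athletes} "
            f"({self.model.groups.n_low} low / {self.model.groups.n_high} high)",
            f"attributes screened: {len(scr)} "
            f"(of {self.model.features.n_attributes}; {len(self.constant_attributes)} constant)",
            f"tests performed: {len(scr)} two-sided Fisher (no multiplicity correction)",
            f"significant discriminators (p < {self.settings.alpha}): "
            f"{int(scr['significant'].sum())}",
            f"commonality candidates: {len(self.commonalities)}",
            f"threshold-selection branches: {scr['branch'].value_counts().to_dict()}",
            f"missing-value exclusions (total): {int(scr['n_excluded'].sum())}",
            "",
            "Summary model (consensus of 4 rankings, top "
            f"{self.settings.top_k}): {len(self.summary_model)} features",
        ]
        if len(self.summary_model):
            lines.append(self.summary_model.table.to_string())
        if self.classifier_report is not None:
            lines += [
                "",
                f"LOOCV classification (positive class = {self.classifier_report.positive_class}):",
                self.classifier_report.display().to_string(),
            ]
        lines += ["", f"seed: {self.settings.seed}  config: {self.settings.config_hash()}"]
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write the bundle as delimited text; returns the artifact paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"seed": self.settings.seed, "config_hash": self.settings.config_hash()}
        paths = {}

        def _write(name: str, frame: pd.DataFrame) -> None:
            path = outdir / f"{name}.csv"
            out = frame.copy()
            for key, val in stamp.items():
                out[key] = val
            out.to_csv(path)
            paths[name] = path

        _write("screening", self.screening)
        _write("discriminators", self.discriminators)
        _write("commonalities", self.commonalities)
        _write("summary_model", self.summary_model.table)
        _write("radar", self.radar)
        if self.classifier_report is not None:
            _write("classifier_report", self.classifier_report.table)
            for kind, preds in (self.classifier_report.predictions or {}).items():
                _write(f"predictions_{kind}", preds)
        labels = pd.DataFrame({"label": self.model.groups.labels})
        if len(self.model.groups.percentiles):
            labels["percentile"] = self.model.groups.percentiles
        _write("labels", labels)
        (outdir / "run_config.json").write_text(
            json.dumps(
                {k: v for k, v in self.settings.__dict__.items() if k != "scales"}
                | {"scales": self.settings.scales.__dict__, "config_hash": self.settings.config_hash()},
                indent=2,
                default=str,
            )
        )
        paths["run_config"] = outdir / "run_config.json"
        return paths
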