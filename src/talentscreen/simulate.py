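"""Synthetic cohorts with the structure the screening analysis assumes.

The generator emulates a 23-low / 6-high athlete cohort profiled on 648
mixed-type developmental attributes across five themes: demographic
counts/indicators, anthropometric deviations from age/sex norms, 1-7 Likert
psychosocial scale scores, hours-per-week training histories (zero-inflated
log-normal) and practice-activity proportions (Dirichlet within families of
four).  Discriminative attributes are *planted* with configurable group
prevalences or mean shifts; everything else is identically distributed in
both groups, so any screening hit on a non-planted attribute is a false
positive by construction.

Performance records and a normative reference population are generated so
the percentile-based grouping stage can be exercised end to end: labels can
either be taken directly from the generator or re-derived from the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import AttributeMeta, Codebook, FeatureTable, NormsTable, validate_records
from .grouping import GroupLabels

DEFAULT_THEME_MIX = {
    "demographics": 0.05,
    "physiology": 0.15,
    "psychosocial": 0.15,
    "sport_history": 0.25,
    "practice_microstructure": 0.40,
}

AGE_GROUPS = ("u15", "u17", "u20")
SEXES = ("m", "f")
BW_CLASSES = ("c1", "c2", "c3", "c4")

#: separation between exposed and unexposed latent values of a planted
#: prevalence-shift attribute, in units of its noise level
_PLANT_MARGIN = 0.25


@dataclass(frozen=True)
class PlantedEffect:
    """A deliberately discriminative attribute.

    ``prevalence_shift`` places a latent threshold at zero and draws each
    athlete above it with group-specific probability (``p_high`` /
    ``p_low``); the idiomatic strong separation of the motivating tables,
    5/6 vs 1/23, is the default.  ``exact=True`` fixes the exposed counts to
    ``round(p * n)`` instead of drawing them.  ``mean_shift`` separates the
    group means by ``effect_size`` standard deviations.
    """

    name: str
    mechanism: Literal["prevalence_shift", "mean_shift"] = "prevalence_shift"
    p_high: float = 5 / 6
    p_low: float = 1 / 23
    effect_size: float = 2.0
    noise_sd: float = 1.0
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_high <= 1 and 0 <= self.p_low <= 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_low: int = 23
    n_high: int = 6
    n_attributes: int = 648
    theme_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THEME_MIX))
    planted_effects: tuple[PlantedEffect, ...] = ()
    missing_rate: float = 0.0
    include_performance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("both groups need at least one athlete")
        if abs(sum(self.theme_mix.values()) - 1.0) > 1e-9:
            raise ValueError("theme mix proportions must sum to 1")
        names = [e.name for e in self.planted_effects]
        if len(set(names)) != len(names):
            raise ValueError(f"planted attribute name collision: {names}")
        if len(names) > self.n_attributes:
            raise ValueError("more planted effects than attributes")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        effects = tuple(PlantedEffect(**e) for e in raw.pop("planted_effects", []))
        return cls(planted_effects=effects, **raw)


@dataclass
class SimulatedCohort:
    features: FeatureTable
    labels: GroupLabels
    records: pd.DataFrame | None
    norms: NormsTable | None
    planted: list[str]
    config: CohortConfig


def _theme_columns(config: CohortConfig) -> list[AttributeMeta]:
    """Allocate attribute names, themes and dtypes per the theme mix."""
    n_planted = len(config.planted_effects)
    n_free = config.n_attributes - n_planted
    counts = {t: int(round(p * n_free)) for t, p in config.theme_mix.items()}
    # rounding drift goes to the largest theme
    drift = n_free - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    metas: list[AttributeMeta] = []
    order = 0
    for effect in config.planted_effects:
        metas.append(AttributeMeta(effect.name, "physiology", "continuous", norm_adjusted=True, order=order))
        order += 1
    demo_cycle = ("binary", "count", "continuous")
    for theme, n in counts.items():
        for i in range(n):
            if theme == "demographics":
                dtype = demo_cycle[i % 3]
            elif theme == "physiology":
                dtype = "continuous"
            elif theme == "psychosocial":
                dtype = "likert_1_7"
            elif theme == "sport_history":
                dtype = "hours_per_week"
            else:  # practice: proportions in families of four, plus volumes
                dtype = "proportion_0_1" if i % 8 < 4 else "hours_per_week"
            metas.append(
                AttributeMeta(
                    f"{theme[:4]}_{i:04d}",
                    theme,
                    dtype,
                    norm_adjusted=theme == "physiology",
                    order=order,
                )
            )
            order += 1
    return metas


def _draw_column(meta: AttributeMeta, n: int, rng: np.random.Generator) -> np.ndarray:
    if meta.dtype == "binary":
        return rng.binomial(1, 0.4, n).astype(float)
    if meta.dtype == "count":
        return rng.poisson(5.0, n).astype(float)
    if meta.dtype == "likert_1_7":
        return np.clip(rng.normal(4.5, 1.2, n), 1.0, 7.0)
    if meta.dtype == "hours_per_week":
        active = rng.random(n) > 0.4  # zero-inflation: many never trained it
        return np.where(active, rng.lognormal(0.5, 0.8, n), 0.0)
    if meta.dtype == "proportion_0_1":
        return rng.beta(2.0, 6.0, n)  # replaced per-family by Dirichlet below
    if meta.theme == "demographics":
        return rng.lognormal(9.5, 1.0, n)  # homeplace-population style
    return rng.normal(0.0, 1.0, n)  # norm deviations


def _planted_column(effect: PlantedEffect, is_high: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = is_high.size
    if effect.mechanism == "mean_shift":
        mu = np.where(is_high, effect.effect_size * effect.noise_sd, 0.0)
        return rng.normal(mu, effect.noise_sd)
    p = np.where(is_high, effect.p_high, effect.p_low)
    if effect.exact:
        exposed = np.zeros(n, dtype=bool)
        for grp, prob in ((is_high, effect.p_high), (~is_high, effect.p_low)):
            idx = np.flatnonzero(grp)
            k = int(round(prob * idx.size))
            exposed[rng.choice(idx, size=k, replace=False)] = True
    else:
        exposed = rng.random(n) < p
    magnitude = np.abs(rng.normal(0.0, effect.noise_sd, n)) + _PLANT_MARGIN * effect.noise_sd
    return np.where(exposed, magnitude, -magnitude)


def generate_reference_population(
    strata: Sequence[tuple] | None = None,
    n_per_stratum: int = 100,
    seed: int = 0,
    base_total: float = 150.0,
    spread: float = 25.0,
) -> NormsTable:
    """Reference totals per (age_group, sex, bodyweight_class) stratum plus
    anthropometric expected values per (age_group, sex)."""
    if n_per_stratum < 10:
        raise ValueError("n_per_stratum must be >= 10")
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = [(a, s, c) for a in AGE_GROUPS for s in SEXES for c in BW_CLASSES]
    samples = {}
    for i, key in enumerate(strata):
        mu = base_total + 10.0 * (i % 7)  # strata differ in level
        samples[tuple(key)] = rng.normal(mu, spread, n_per_stratum)
    expected = {}
    for a in AGE_GROUPS:
        for s in SEXES:
            expected[(a, s)] = float(rng.normal(100.0, 5.0))
    return NormsTable(expected=expected, reference_samples=samples)


def _records_for(
    athletes: pd.Index,
    is_high: np.ndarray,
    strata: list[tuple],
    norms: NormsTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Competition records whose best-total percentile matches the label."""
    rows = []
    for athlete, high, stratum in zip(athletes, is_high, strata):
        sample = np.sort(norms.reference_sample(stratum))
        n_comp = int(rng.integers(1, 4))
        if high:  # best performance clears the 80th percentile
            best = sample[int(np.ceil(0.8 * sample.size)) - 1] + rng.uniform(0.5, 10.0)
        else:  # stays strictly below it
            best = sample[max(int(np.ceil(0.8 * sample.size)) - 2, 0)] - rng.uniform(0.5, 10.0)
        totals = np.sort(rng.uniform(best * 0.85, best, n_comp))
        totals[-1] = best
        for j, total in enumerate(totals):
            total = round(float(total), 1)
            snatch = round(total * 0.45, 1)
            rows.append(
                {
                    "athlete_id": athlete,
                    "date": f"2020-{j + 1:02d}-15",
                    "snatch_kg": snatch,
                    "clean_and_jerk_kg": round(total - snatch, 1),
                    "total_kg": total,
                    "sex": stratum[1],
                    "age_group": stratum[0],
                    "bodyweight_class": stratum[2],
                }
            )
    return validate_records(pd.DataFrame(rows))


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate one cohort; bit-reproducible for a given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_low + config.n_high
    athletes = pd.Index([f"ath{i:03d}" for i in range(1, n + 1)], name="athlete_id")
    is_high = np.zeros(n, dtype=bool)
    is_high[rng.choice(n, size=config.n_high, replace=False)] = True

    metas = _theme_columns(config)
    codebook = Codebook(metas)
    effects = {e.name: e for e in config.planted_effects}
    columns: dict[str, np.ndarray] = {}
    for meta in metas:
        if meta.name in effects:
            columns[meta.name] = _planted_column(effects[meta.name], is_high, rng)
        else:
            columns[meta.name] = _draw_column(meta, n, rng)
    # practice proportions come from a Dirichlet within each family of four
    prop_cols = [m.name for m in metas if m.dtype == "proportion_0_1"]
    for start in range(0, len(prop_cols) - len(prop_cols) % 4, 4):
        family = prop_cols[start : start + 4]
        shares = rng.dirichlet(np.ones(4), size=n)
        for j, name in enumerate(family):
            columns[name] = shares[:, j]

    data = pd.DataFrame(columns, index=athletes)
    if config.missing_rate > 0:
        mask = rng.random(data.shape) < config.missing_rate
        data = data.mask(mask)
    features = FeatureTable(data, codebook)

    labels = GroupLabels(
        labels=pd.Series(np.where(is_high, "high", "low"), index=athletes),
        threshold=80.0,
    )

    records = norms = None
    if config.include_performance:
        norms = generate_reference_population(seed=int(rng.integers(2**31 - 1)))
        strata_pool = [(a, s, c) for a in AGE_GROUPS for s in SEXES for c in BW_CLASSES]
        strata = [strata_pool[i] for i in rng.integers(0, len(strata_pool), n)]
        records = _records_for(athletes, is_high, strata, norms, rng)

    return SimulatedCohort(
        features=features,
        labels=labels,
        records=records,
        norms=norms,
        planted=list(effects),
        config=config,
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Convenience for replicate loops."""
    return replace(config, seed=seed)
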