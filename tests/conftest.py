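"""Shared fixtures: published regression rows and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import talentscreen as ts

# ---------------------------------------------------------------------------
# Published discriminator rows, used as a regression fixture for the
# small-sample-adjusted odds ratio and the importance grading.  Each row is
# (rule, exposed_high a, exposed_low b, printed OR, printed importance) with
# group sizes 6 high / 23 low.  `anomalous=True` marks the single published
# row whose printed OR the verified formula does not reproduce (suspected
# erratum); it is excluded from value assertions.
# ---------------------------------------------------------------------------

PUBLISHED_ROWS = [
    # demographics & familial sport participation
    ("homeplace population 6-12y high", 5, 6, 6.07, "High", False),
    ("school main place for sport 6-12y", 4, 1, 14.67, "High", False),
    # anthropometrics & physiology
    ("height change T1-T2 above norm", 4, 2, 9.33, "High", False),
    ("tibia length above norm", 2, 0, 9.20, "Moderate", False),
    ("total arm to height ratio above norm", 6, 7, 12.00, "High", False),
    ("torso length change above norm", 3, 1, 8.25, "Moderate", False),
    ("tibia length change above norm", 5, 6, 6.07, "High", False),
    ("arm ratio change below norm", 2, 0, 9.20, "Moderate", False),
    ("CMJ peak power (Duncan) T1 above norm", 5, 6, 6.07, "High", False),
    ("standing broad jump above norm", 4, 4, 5.07, "High", False),
    ("CMJ peak power (Sayers) T2 above norm", 5, 6, 6.07, "High", False),
    ("CMJ peak power (Duncan) T2 above norm", 5, 6, 6.07, "High", False),
    ("CMJ height T2 above norm", 5, 6, 6.07, "High", False),
    ("squat jump height T2 above norm", 2, 0, 9.20, "Moderate", False),
    ("back squat ratio T1 above norm", 3, 1, 8.25, "Moderate", False),
    ("front squat ratio T1 above norm", 6, 8, 10.00, "High", False),
    ("back squat ratio T2 above norm", 2, 0, 9.20, "Moderate", False),
    ("front squat ratio T2 above norm", 3, 2, 5.25, "Moderate", False),
    ("back squat ratio change above norm", 0, 12, 0.00, "Low", False),
    ("overhead squat torso angle", 2, 0, 9.20, "Moderate", False),
    # psychosocial
    ("mastery approach >= 6", 3, 1, 8.25, "Moderate", False),
    ("mastery avoidance >= 4", 2, 21, 0.04, "High", False),
    ("performance approach >= 6", 4, 4, 5.07, "High", False),
    ("commitment to training > 4.7", 6, 10, 7.09, "High", False),
    ("total preparation > 5.15", 3, 6, 1.82, "", False),
    ("relative importance of sport > 3.55", 6, 10, 7.09, "High", False),
    ("harmonious passion > 5.72", 5, 2, 17.50, "High", False),
    ("obsessive passion > 4.63", 5, 4, 9.50, "High", False),
    ("conscientiousness > 5.81", 5, 5, 7.50, "High", False),
    ("openness to experience > 6.59", 2, 0, 9.20, "Moderate", False),
    ("extraversion > 5.21", 6, 9, 8.40, "High", False),
    ("doubts about actions > 2.35", 0, 22, 0.00, "High", False),
    ("organization > 5.61", 5, 2, 17.50, "High", False),
    # sport participation through development
    ("flex/mob age 10", 2, 0, 9.20, "Moderate", False),
    ("flex/mob age 11", 2, 0, 9.20, "Moderate", False),
    ("flex/mob age 12", 2, 0, 9.20, "Moderate", False),
    ("flex/mob age 13", 2, 0, 9.20, "Moderate", False),
    ("flex/mob age 14", 4, 0, 30.67, "High", False),
    ("flex/mob age 15", 3, 0, 17.25, "High", False),
    ("S&C age 9", 2, 0, 9.20, "Moderate", False),
    ("S&C age 10", 2, 0, 9.20, "Moderate", False),
    ("S&C age 15", 3, 1, 8.25, "Moderate", False),
    ("combined training age 13", 2, 17, 0.06, "Low", True),  # suspected erratum
    ("combined training age 15", 5, 3, 12.50, "High", False),
    ("cumulative flex/mob T1", 3, 0, 17.25, "High", False),
    ("cumulative S&C T1", 3, 0, 17.25, "High", False),
    ("cumulative WL practice T1", 5, 4, 9.50, "High", False),
    ("competitions by T1 > 8", 6, 8, 10.00, "High", False),
    ("competition time T1", 5, 4, 9.50, "High", False),
    ("cumulative flex/mob T2", 4, 1, 14.67, "High", False),
    ("cumulative S&C T2", 3, 1, 8.25, "High", False),
    ("cumulative WL practice T2", 4, 2, 9.33, "High", False),
    ("competitions by T2 > 10", 6, 8, 10.00, "High", False),
    ("competition time T2", 5, 3, 12.50, "High", False),
    ("flex/mob practice T1-T2", 6, 5, 18.00, "High", False),
    ("WL practice T1-T2", 3, 2, 5.25, "High", False),
]

N_HIGH, N_LOW = 6, 23


def published_counts(a: int, b: int) -> ts.ContingencyCounts:
    return ts.ContingencyCounts(a, b, N_HIGH - a, N_LOW - b)


@pytest.fixture(scope="session")
def published_rows():
    return PUBLISHED_ROWS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """29-athlete cohort with two planted effects, reused across tests."""
    cfg = ts.CohortConfig(
        n_attributes=40,
        planted_effects=(
            ts.PlantedEffect("planted_prev"),
            ts.PlantedEffect("planted_mean", mechanism="mean_shift", effect_size=2.5),
        ),
        seed=42,
    )
    return ts.generate_cohort(cfg)


@pytest.fixture()
def toy_labels():
    """10 athletes, 3 high / 7 low."""
    idx = pd.Index([f"a{i}" for i in range(10)], name="athlete_id")
    lab = pd.Series(["high"] * 3 + ["low"] * 7, index=idx)
    return ts.GroupLabels.from_series(lab)
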