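"""Synthetic epidemiological inputs and trial trajectories.

The model's real-world inputs (national BMI distributions, mortality life
tables, per-disease incidence and relative risks, trial weight-change
series) are external data sets.  This module generates tables with the same
statistical structure so the engine can be exercised, validated and
stress-tested end to end:

* incidence and all-cause mortality rise with age,
* relative risks are non-decreasing across BMI categories (by construction,
  via positive per-category increments) and rise mildly with age,
* every BMI is >= 35 kg/m^2 at entry (Gamma-distributed excess over 35),
* one disease is flagged ``rr_tracks_fatality`` — the convention for a
  cancer whose survival is so poor that the relative risk of developing it
  is taken equal to the relative risk of dying from it.

A single ``severity`` scalar multiplies baseline incidence and the RR
gradients.  At ``severity=1`` the default tables produce, per 100,000
persons over 30 years, a cumulative incident-case count of the same order
of magnitude as a severely obese national cohort (a few hundred thousand);
``severity -> 0`` drives disease incidence to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epi import (
    AGE_BAND_LOWER,
    AGE_BANDS,
    DEFAULT_BMI_CUTS,
    DiseaseDefinition,
    EpiParameterSet,
    InputError,
    SEXES,
    category_labels,
)
from .trajectories import TrajectorySpec

# Relative size of each 5-year age band in the synthetic adult population
# (roughly pyramid-shaped, thinning beyond retirement age).
_AGE_WEIGHTS = np.array(
    [0.90, 1.00, 1.05, 1.05, 1.00, 1.00, 0.95, 0.90, 0.85, 0.75, 0.60, 0.45, 0.30, 0.18]
)


@dataclass
class SyntheticTrial:
    """A synthetic weight-management trial with known ground truth.

    ``true_delta_series`` holds the noise-free annual BMI change;
    ``observed_points`` are sparse, noisy measurements of it, anchored at
    (0, 0) exactly (the trial baseline).  Used for parameter-recovery tests
    of the fitted-trend regain rule.
    """

    true_delta_series: pd.Series
    observed_points: list[tuple[float, float]]
    noise_sd: float


def generate_epi_tables(
    seed: int, n_diseases: int = 12, severity: float = 1.0
) -> EpiParameterSet:
    """Generate a complete, schema-valid synthetic :class:`EpiParameterSet`.

    Deterministic for a fixed ``seed``.  ``severity`` (> 0) scales baseline
    incidence probabilities and the per-category RR increments.
    """
    if n_diseases < 1:
        raise InputError(f"n_diseases must be >= 1, got {n_diseases}")
    if severity <= 0:
        raise InputError(f"severity must be > 0, got {severity}")
    rng = np.random.default_rng(seed)

    # Population composition: age pyramid x a near-even sex split.
    w = _AGE_WEIGHTS * rng.uniform(0.95, 1.05, size=len(AGE_BANDS))
    sex_split = rng.uniform(0.47, 0.53)
    props = np.outer(w / w.sum(), [sex_split, 1.0 - sex_split])
    props /= props.sum()
    population = pd.DataFrame(
        [
            {"age_band": b, "sex": s, "proportion": props[i, j]}
            for i, b in enumerate(AGE_BANDS)
            for j, s in enumerate(SEXES)
        ]
    )

    # BMI excess over 35: Gamma with mean excess ~3.5-5 kg/m^2.
    bmi_rows = []
    trend_rows = []
    for b in AGE_BANDS:
        for s in SEXES:
            bmi_rows.append(
                {
                    "age_band": b,
                    "sex": s,
                    "excess_shape": rng.uniform(1.3, 1.8),
                    "excess_scale": rng.uniform(2.2, 3.2),
                }
            )
            trend_rows.append(
                {"age_band": b, "sex": s, "logit_drift": rng.uniform(0.005, 0.02)}
            )
    bmi_distribution = pd.DataFrame(bmi_rows)
    bmi_trend = pd.DataFrame(trend_rows)

    # All-cause mortality: Gompertz-like in age, lower for women.
    a0 = rng.uniform(4e-4, 7e-4)
    b0 = rng.uniform(0.085, 0.095)
    mort_rows = []
    for i, band in enumerate(AGE_BANDS):
        base = min(a0 * np.exp(b0 * (AGE_BAND_LOWER[i] - 20)), 0.5)
        for s, mult in zip(SEXES, (1.0, 0.85)):
            mort_rows.append({"age_band": band, "sex": s, "annual_prob": base * mult})
    all_cause_mortality = pd.DataFrame(mort_rows)

    diseases = [
        _generate_disease(rng, k, n_diseases, severity) for k in range(n_diseases)
    ]
    return EpiParameterSet(
        population=population,
        bmi_distribution=bmi_distribution,
        bmi_trend=bmi_trend,
        all_cause_mortality=all_cause_mortality,
        diseases=diseases,
    ).require_valid()


def _generate_disease(
    rng: np.random.Generator, k: int, n_diseases: int, severity: float
) -> DiseaseDefinition:
    labels = category_labels(DEFAULT_BMI_CUTS)
    did = f"disease_{k + 1:02d}"

    sexes = "both"
    if n_diseases >= 6 and rng.uniform() < 0.2:
        sexes = "female_only"

    # Baseline incidence rises exponentially with age; a sex ratio tilts it.
    r0 = float(np.exp(rng.normal(np.log(1.5e-3), 0.7)))
    grad = rng.uniform(0.025, 0.055)
    sex_ratio = rng.uniform(0.7, 1.3)
    inc_rows = []
    for i, band in enumerate(AGE_BANDS):
        base = min(r0 * severity * np.exp(grad * (AGE_BAND_LOWER[i] - 20)), 0.3)
        for s in SEXES:
            p = 0.0 if not _applies(sexes, s) else base * (sex_ratio if s == "female" else 1.0)
            inc_rows.append(
                {
                    "age_band": band,
                    "sex": s,
                    "annual_prob": min(p, 0.3),
                    "initial_prevalence": 0.0,
                }
            )
    incidence = pd.DataFrame(inc_rows)

    # RR per (age band, BMI category): positive increments per category keep
    # monotonicity in BMI; a mild positive age factor keeps monotonicity in age.
    increments = rng.uniform(0.08, 0.45, size=len(labels) - 1) * severity
    rr_rows = []
    for i, band in enumerate(AGE_BANDS):
        age_factor = 1.0 + 0.004 * (AGE_BAND_LOWER[i] - 20)
        rr = np.concatenate([[1.0], 1.0 + np.cumsum(increments) * age_factor])
        rr_rows += [
            {"age_band": band, "bmi_category": c, "rr": rr[j]}
            for j, c in enumerate(labels)
        ]
    rr_by_bmi = pd.DataFrame(rr_rows)

    f0 = min(float(np.exp(rng.normal(np.log(0.01), 1.0))), 0.3)
    fat_rows = []
    for i, band in enumerate(AGE_BANDS):
        q = min(f0 * np.exp(0.05 * (AGE_BAND_LOWER[i] - 20)), 0.6)
        for s in SEXES:
            fat_rows.append(
                {"age_band": band, "sex": s, "annual_prob": q if _applies(sexes, s) else 0.0}
            )
    case_fatality = pd.DataFrame(fat_rows)

    u = round(rng.uniform(0.55, 0.95), 3)
    utility = {
        "male": u if _applies(sexes, "male") else float("nan"),
        "female": u if _applies(sexes, "female") else float("nan"),
    }
    return DiseaseDefinition(
        id=did,
        name=f"Synthetic disease {k + 1}",
        incidence=incidence,
        rr_by_bmi=rr_by_bmi,
        case_fatality=case_fatality,
        annual_cost=round(float(np.exp(rng.normal(np.log(2000.0), 0.8))), 2),
        utility=utility,
        sexes=sexes,
        # Last disease plays the poor-survival-cancer role: its incidence RR
        # is reused as its mortality RR.
        rr_tracks_fatality=(k == n_diseases - 1 and n_diseases >= 2),
    )


def _applies(sexes: str, sex: str) -> bool:
    return sexes == "both" or sexes == f"{sex}_only"


def generate_trial(
    seed: int,
    effect: Mapping[float, float] | pd.Series,
    noise_sd: float,
    times: Sequence[float],
) -> SyntheticTrial:
    """Sample noisy observations of a known BMI-change series.

    ``effect`` maps time (years since delivery) to the true ΔBMI; ``times``
    must be a subset of its support.  The baseline observation (0, 0) is
    exact; later observations get iid Gaussian noise with SD ``noise_sd``.
    """
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    series = pd.Series(dict(effect)).sort_index() if not isinstance(effect, pd.Series) else effect.sort_index()
    times = sorted(float(t) for t in times)
    if len(times) != len(set(times)):
        raise InputError("times must be strictly increasing (duplicates found)")
    missing = [t for t in times if t not in series.index]
    if missing:
        raise InputError(f"times {missing} not in the support of the effect series")
    if times and times[0] == 0.0:
        times = times[1:]
    rng = np.random.default_rng(seed)
    observed = [(0.0, 0.0)] + [
        (t, float(series.loc[t] + rng.normal(0.0, noise_sd))) for t in times
    ]
    return SyntheticTrial(
        true_delta_series=series, observed_points=observed, noise_sd=float(noise_sd)
    )


# ---------------------------------------------------------------------------
# Demo trajectories

#: SYNTHETIC demo BMI-change observations (years since delivery, ΔBMI in
#: kg/m^2).  These are constructed stand-ins with field-plausible shapes —
#: modest ~1-unit loss for short behavioural programmes, a larger sustained
#: loss with partial regain for intensive lifestyle support, and a deep
#: sustained loss with slow creep for gastric-bypass surgery — not values
#: from any trial.
SYNTHETIC_DEMO_POINTS: dict[str, list[tuple[float, float]]] = {
    "wmp1": [(0.0, 0.0), (1.0, -1.0)],
    "vlcd_wmp1": [(0.0, 0.0), (1.0, -1.4)],
    "wmp2": [(0.0, 0.0), (1.0, -1.3), (2.0, -0.9)],
    "look_ahead": [(0.0, 0.0), (1.0, -2.3), (4.0, -1.5), (8.0, -1.6)],
    "rygb": [
        (0.0, 0.0),
        (1.0, -11.0),
        (2.0, -12.0),
        (6.0, -10.0),
        (10.0, -9.0),
        (15.0, -8.5),
        (20.0, -8.0),
    ],
}


def demo_trajectories(
    horizon: int = 30, regain_rule: str = "five_year"
) -> dict[str, TrajectorySpec]:
    """Synthetic demo trajectory specs for the five modelled interventions.

    Non-surgical interventions use ``regain_rule``; surgery always uses
    linear extrapolation of its long-follow-up tail (its regain was observed
    rather than assumed, so the sensitivity switch does not touch it).
    """
    specs = {}
    for name, pts in SYNTHETIC_DEMO_POINTS.items():
        rule = "surgical_extrapolation" if name == "rygb" else regain_rule
        specs[name] = TrajectorySpec(
            name=name, observed_points=list(pts), regain_rule=rule, horizon=horizon
        )
    return specs
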