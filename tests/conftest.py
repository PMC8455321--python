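"""Shared fixtures: synthetic parameter sets and a flat-rate builder.

``make_flat_epi`` constructs a parameter set with rates constant across
age and sex, which makes the microsimulation analytically tractable: the
per-person process becomes a small time-homogeneous Markov chain that the
oracle tests solve exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from obesim.epi import AGE_BANDS, DEFAULT_BMI_CUTS, DiseaseDefinition, EpiParameterSet, SEXES, category_labels
from obesim.synth import generate_epi_tables
from obesim.cohort import sample_cohort


def make_flat_epi(
    disease_specs: list[dict],
    mortality: float = 0.0,
    drift: float = 0.0,
    excess_shape: float = 1.5,
    excess_scale: float = 2.5,
) -> EpiParameterSet:
    """Parameter set with rates constant across age bands and sexes.

    Each disease spec accepts: ``id``, ``p_inc``, ``p_fat`` (default 0),
    ``cost`` (default 0), ``utility`` (default 1), ``rr`` (scalar or one
    value per BMI category, default all 1), ``rr_tracks_fatality``.
    """
    labels = category_labels(DEFAULT_BMI_CUTS)
    grid = [(b, s) for b in AGE_BANDS for s in SEXES]
    population = pd.DataFrame(
        [{"age_band": b, "sex": s, "proportion": 1.0 / len(grid)} for b, s in grid]
    )
    bmi_distribution = pd.DataFrame(
        [
            {"age_band": b, "sex": s, "excess_shape": excess_shape, "excess_scale": excess_scale}
            for b, s in grid
        ]
    )
    bmi_trend = pd.DataFrame(
        [{"age_band": b, "sex": s, "logit_drift": drift} for b, s in grid]
    )
    all_cause = pd.DataFrame(
        [{"age_band": b, "sex": s, "annual_prob": mortality} for b, s in grid]
    )
    diseases = []
    for spec in disease_specs:
        rr = spec.get("rr", 1.0)
        rr_vec = np.full(len(labels), float(rr)) if np.isscalar(rr) else np.asarray(rr, float)
        rr_vec[0] = 1.0
        diseases.append(
            DiseaseDefinition(
                id=spec["id"],
                name=spec["id"],
                incidence=pd.DataFrame(
                    [{"age_band": b, "sex": s, "annual_prob": spec["p_inc"]} for b, s in grid]
                ),
                rr_by_bmi=pd.DataFrame(
                    [
                        {"age_band": b, "bmi_category": c, "rr": rr_vec[j]}
                        for b in AGE_BANDS
                        for j, c in enumerate(labels)
                    ]
                ),
                case_fatality=pd.DataFrame(
                    [
                        {"age_band": b, "sex": s, "annual_prob": spec.get("p_fat", 0.0)}
                        for b, s in grid
                    ]
                ),
                annual_cost=spec.get("cost", 0.0),
                utility={"male": spec.get("utility", 1.0), "female": spec.get("utility", 1.0)},
                sexes=spec.get("sexes", "both"),
                rr_tracks_fatality=spec.get("rr_tracks_fatality", False),
            )
        )
    return EpiParameterSet(
        population=population,
        bmi_distribution=bmi_distribution,
        bmi_trend=bmi_trend,
        all_cause_mortality=all_cause,
        diseases=diseases,
    ).require_valid()


@pytest.fixture(scope="session")
def epi_small() -> EpiParameterSet:
    """Small synthetic parameter set shared across tests."""
    return generate_epi_tables(seed=11, n_diseases=3, severity=1.0)


@pytest.fixture(scope="session")
def cohort_small(epi_small):
    return sample_cohort(epi_small, 5_000, seed=2)
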