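"""Closed-cohort construction and counterfactual BMI projection.

The cohort is sampled once, at entry (default calendar year 2016), from the
age x sex composition of the severely obese adult population, and is closed
thereafter: members leave only through death.  Each individual receives a
BMI *percentile* within their age-sex stratum, fixed at entry.  Their
counterfactual (no-intervention) BMI in any later year is obtained by
quantile mapping: the same percentile evaluated in the stratum's projected
BMI distribution for that year.  Quantile mapping is the minimal rule that
reproduces the projected category proportions while giving every individual
a coherent longitudinal path — it is monotone in the percentile and reduces
to the identity when the trend drift is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epi import (
    AGE_BAND_LOWER,
    CompiledEpi,
    EpiParameterSet,
    InputError,
    N_BANDS,
    SEXES,
    band_of_age,
)


@dataclass
class Individual:
    """A read-only snapshot of one simulated person."""

    id: int
    sex: str
    age: int
    bmi_percentile: float
    baseline_bmi: float
    disease_state: dict[str, int] = field(default_factory=dict)  # disease id -> onset year
    alive: bool = True


@dataclass
class Cohort:
    """The closed virtual cohort at entry.

    State is stored as parallel arrays; ``cohort[i]`` materialises an
    :class:`Individual` view for inspection.
    """

    entry_year: int
    age: np.ndarray  # entry age, int
    sex: np.ndarray  # 0 = male, 1 = female
    bmi_percentile: np.ndarray  # fixed at entry, in (0, 1)
    baseline_bmi: np.ndarray  # BMI at entry, >= 35

    @property
    def size(self) -> int:
        return len(self.age)

    @property
    def per_100k(self) -> float:
        return 100_000.0 / self.size

    def __len__(self) -> int:
        return self.size

    def __getitem__(self, i: int) -> Individual:
        return Individual(
            id=int(i),
            sex=SEXES[int(self.sex[i])],
            age=int(self.age[i]),
            bmi_percentile=float(self.bmi_percentile[i]),
            baseline_bmi=float(self.baseline_bmi[i]),
        )


def sample_cohort(epi: EpiParameterSet, n: int, seed: int) -> Cohort:
    """Draw ``n`` individuals from the age x sex x BMI entry distribution.

    Age-sex cell membership follows the population proportions in
    expectation; ages are uniform within their 5-year band; BMI percentiles
    are uniform, so entry BMI follows the stratum's 35-plus-Gamma law
    exactly.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise InputError(f"cohort size must be >= 1, got {n}")
    compiled = epi.compile(horizon_years=1)
    rng = np.random.default_rng(seed)

    probs = compiled.population.ravel()
    cells = rng.choice(len(probs), size=n, p=probs / probs.sum())
    band = cells // 2
    sex = (cells % 2).astype(np.int8)
    age = AGE_BAND_LOWER[band] + rng.integers(0, 5, size=n)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=n)
    bmi0 = compiled.bmi_at(band, sex, u, np.zeros(n, dtype=np.intp))
    return Cohort(
        entry_year=2016,
        age=age.astype(np.int64),
        sex=sex,
        bmi_percentile=u,
        baseline_bmi=bmi0,
    )


def project_baseline_bmi(
    individual: Individual, epi: EpiParameterSet | CompiledEpi, year: int, entry_year: int = 2016
) -> float:
    """Counterfactual BMI of one individual in a given calendar year.

    The individual's fixed percentile is mapped through the projected BMI
    distribution of the age band they occupy in that year.
    """
    t = year - entry_year
    if t < 0:
        raise InputError(f"year {year} precedes cohort entry ({entry_year})")
    if not individual.alive:
        raise InputError("cannot project BMI for a dead individual")
    compiled = epi if isinstance(epi, CompiledEpi) else epi.compile(t + 1)
    age_t = individual.age + t
    band = band_of_age(age_t)
    s = SEXES.index(individual.sex)
    return float(
        compiled.bmi_at(
            np.asarray([band]), np.asarray([s]), np.asarray([individual.bmi_percentile]),
            np.asarray([min(t, compiled.horizon - 1)]),
        )[0]
    )


def project_cohort_bmi(
    compiled: CompiledEpi,
    age: np.ndarray,
    sex: np.ndarray,
    u: np.ndarray,
    t_index: int,
) -> np.ndarray:
    """Vectorised counterfactual BMI for a whole cohort at offset ``t_index``."""
    band = band_of_age(age)
    return compiled.bmi_at(band, sex, u, np.full(len(age), t_index, dtype=np.intp))
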