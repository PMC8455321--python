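"""The annual-cycle semi-Markov Monte-Carlo engine.

Each individual is simulated through annual cycles over the model horizon.
Within a cycle the event order is:

1. age and effective BMI are updated (counterfactual quantile-mapped BMI
   plus the scenario's ΔBMI, floored);
2. each absent, sex-applicable disease may occur, with probability
   ``min(base_incidence(age, sex) x RR(age band, BMI category), 1)``;
3. death is drawn from the combined all-cause and per-disease case-fatality
   hazards, assumed independent on the probability scale:
   ``q = 1 - (1 - q_allcause) * prod_d (1 - q_fatality_d)``;
4. tallies are recorded.

Diseases persist for life once acquired (semi-Markov persistence, no
remission) and death is absorbing.  Uniform draws are made for the full
individual x disease matrix every cycle regardless of state, so two runs
with the same seed consume the random stream identically — this makes a
shared seed act as common random numbers across scenarios and guarantees
that a scenario with ΔBMI identically zero reproduces the baseline run
draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import econ
from .cohort import Cohort
from .epi import (
    CompiledEpi,
    DEFAULT_BMI_CUTS,
    DEFAULT_BMI_FLOOR,
    DiseaseDefinition,
    EpiParameterSet,
    InputError,
    band_of_age,
    bmi_category,
    sex_index,
)

__all__ = [
    "DiseaseDefinition",
    "SimulationConfig",
    "SimulationTrace",
    "SimulationResult",
    "incidence_probability",
    "annual_cycle",
    "run_simulation",
    "summarize_incidence",
]


@dataclass
class SimulationConfig:
    """Run-level settings for one simulation."""

    start_year: int = 2016
    horizon_years: int = 30
    discount_rate: float = 0.015
    seed: int = 0
    cohort_size: int = 100_000
    bmi_category_cuts: tuple[float, ...] = DEFAULT_BMI_CUTS
    regain_rule: str = "five_year"
    bmi_floor: float = DEFAULT_BMI_FLOOR
    keep_trace: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise InputError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.discount_rate < 0:
            raise InputError(f"discount_rate must be >= 0, got {self.discount_rate}")


@dataclass
class SimulationTrace:
    """Compact per-individual history: disease onset cycles and death cycle.

    ``onset_year[i, d]`` is the 1-based cycle in which individual ``i``
    acquired disease ``d`` (0 for prevalent-at-entry, -1 for never);
    ``death_year[i]`` is the cycle of death (-1 if alive at the horizon).
    """

    disease_ids: list[str]
    onset_year: np.ndarray  # (n, d) int16
    death_year: np.ndarray  # (n,) int16
    sex: np.ndarray  # (n,) int8
    horizon: int

    @property
    def n(self) -> int:
        return len(self.death_year)


@dataclass
class _EngineState:
    """Mutable cohort state threaded through :func:`annual_cycle`."""

    age: np.ndarray
    sex: np.ndarray
    u: np.ndarray  # BMI percentile, fixed
    alive: np.ndarray  # bool
    onset: np.ndarray  # (n, d) int16, -1 = absent
    death_year: np.ndarray  # (n,) int16, -1 = alive
    band: np.ndarray  # current age-band index
    z: np.ndarray  # cached unit-scale Gamma quantile for the current band


@dataclass
class SimulationResult:
    """Outputs of one scenario run."""

    scenario: str
    config: SimulationConfig
    n: int
    incident_cases: pd.DataFrame  # index: model year 1..T; columns: disease ids
    deaths_by_year: np.ndarray
    alive_by_year: np.ndarray  # alive at the END of each cycle
    economics: econ.EconomicsResult
    incidence_summary: pd.DataFrame  # per disease: cases, mean, variance
    trace: SimulationTrace | None = None

    @property
    def cumulative_cases(self) -> pd.Series:
        return self.incident_cases.sum(axis=0)

    @property
    def total_cases(self) -> int:
        return int(self.incident_cases.to_numpy().sum())

    @property
    def per_100k(self) -> float:
        return 100_000.0 / self.n

    @property
    def total_cases_per_100k(self) -> float:
        return self.total_cases * self.per_100k

    def totals_frame(self) -> pd.DataFrame:
        """One-row frame of headline discounted totals, per 100k."""
        e = self.economics
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario,
                    "cumulative_cases_per_100k": self.total_cases_per_100k,
                    "deaths_per_100k": float(self.deaths_by_year.sum()) * self.per_100k,
                    "intervention_cost_per_100k": e.intervention_cost_per_100k,
                    "disease_cost_per_100k": e.disease_cost_per_100k,
                    "total_cost_per_100k": e.total_cost_per_100k,
                    "qalys_per_100k": e.qalys_per_100k,
                }
            ]
        )


def incidence_probability(
    disease: DiseaseDefinition,
    age: int,
    sex: str,
    bmi: float,
    cuts: tuple[float, ...] = DEFAULT_BMI_CUTS,
) -> float:
    """Annual probability of incidence for one individual, capped at 1.

    ``p = min(base_incidence(age, sex) * RR(age band, BMI category), 1)``.
    """
    if bmi <= 0:
        raise InputError(f"bmi must be positive, got {bmi}")
    if not disease.applicable_to(sex):
        raise InputError(f"disease {disease.id} does not apply to sex {sex!r}")
    band_label = _band_label(age)
    inc = disease.incidence
    base = inc[(inc["age_band"] == band_label) & (inc["sex"] == sex)]["annual_prob"]
    if base.empty:
        raise InputError(f"no incidence entry for age_band={band_label}, sex={sex}")
    cat_label = _category_label(bmi, cuts)
    rr_df = disease.rr_by_bmi
    rr = rr_df[(rr_df["age_band"] == band_label) & (rr_df["bmi_category"] == cat_label)]["rr"]
    if rr.empty:
        raise InputError(f"no RR entry for age_band={band_label}, bmi_category={cat_label}")
    return min(float(base.iloc[0]) * float(rr.iloc[0]), 1.0)


def _band_label(age: int) -> str:
    from .epi import AGE_BANDS

    return AGE_BANDS[int(band_of_age(age))]


def _category_label(bmi: float, cuts: tuple[float, ...]) -> str:
    from .epi import category_labels

    return category_labels(cuts)[int(bmi_category(bmi, cuts))]


def summarize_incidence(cases: int, n_trials: int) -> tuple[float, float]:
    """Binomial summary of incidence: (mean proportion, variance of the mean)."""
    if n_trials < 1:
        raise InputError(f"n_trials must be >= 1, got {n_trials}")
    if not 0 <= cases <= n_trials:
        raise InputError(f"cases={cases} outside [0, {n_trials}]")
    mean = cases / n_trials
    return mean, mean * (1.0 - mean) / n_trials


def annual_cycle(
    state: _EngineState,
    t: int,
    delta_t: float,
    compiled: CompiledEpi,
    rng: np.random.Generator,
    bmi_floor: float = DEFAULT_BMI_FLOOR,
) -> dict:
    """Advance the cohort one cycle; returns the cycle tally.

    ``t`` is the 1-based model year; ``delta_t`` the scenario ΔBMI applied
    during it.  Mutates ``state`` in place.
    """
    alive = state.alive
    # (1) age update (cycle 1 uses the entry age) and effective BMI.
    if t > 1:
        state.age[alive] += 1
    new_band = band_of_age(state.age)
    changed = (new_band != state.band) & alive
    if changed.any():
        state.z[changed] = compiled.standard_quantile(
            new_band[changed], state.sex[changed], state.u[changed]
        )
    state.band = new_band
    theta_t = compiled.theta[state.band, state.sex, min(t - 1, compiled.horizon - 1)]
    bmi = np.maximum(35.0 + theta_t * state.z + delta_t, bmi_floor)
    cat = bmi_category(bmi, compiled.cuts)

    n, nd = state.onset.shape
    draws = rng.uniform(size=(n, nd))
    base = compiled.incidence[:, state.band, state.sex].T  # (n, d)
    rr = compiled.rr[:, state.band, cat].T
    p = np.minimum(base * rr, 1.0)
    eligible = alive[:, None] & (state.onset < 0) & compiled.applicable[:, state.sex].T
    new_cases = eligible & (draws < p)
    state.onset[new_cases] = t

    # (3) combined mortality: all-cause and case fatality of present diseases.
    q_all = compiled.mortality[state.band, state.sex]
    fat = compiled.fatality[:, state.band, state.sex].T
    fat = np.where(compiled.rr_tracks_fatality[None, :], np.minimum(fat * rr, 1.0), fat)
    present = state.onset >= 0
    surv = (1.0 - q_all) * np.prod(np.where(present, 1.0 - fat, 1.0), axis=1)
    dies = alive & (rng.uniform(size=n) < 1.0 - surv)
    state.death_year[dies] = t
    state.alive[dies] = False

    return {
        "incident": new_cases.sum(axis=0),
        "deaths": int(dies.sum()),
        "alive_end": int(state.alive.sum()),
    }


def run_simulation(
    config: SimulationConfig,
    cohort: Cohort,
    profile: "econ.InterventionProfile | None",
    epi: EpiParameterSet | CompiledEpi,
) -> SimulationResult:
    """Run one scenario over the full horizon; deterministic for a fixed seed.

    ``profile=None`` runs the baseline (no delivery cost, ΔBMI = 0); the
    same is reproduced exactly by any profile whose ΔBMI series is all
    zeros and whose schedule is empty, under the same seed.
    """
    T = config.horizon_years
    compiled = epi if isinstance(epi, CompiledEpi) else epi.compile(T)
    if tuple(compiled.cuts) != tuple(config.bmi_category_cuts):
        raise InputError("config.bmi_category_cuts disagree with the compiled parameter set")
    delta = profile.annual_delta(T) if profile is not None else np.zeros(T)

    rng = np.random.default_rng(config.seed)
    n = cohort.size
    nd = len(compiled.disease_ids)
    state = _EngineState(
        age=cohort.age.copy(),
        sex=cohort.sex.astype(np.intp),
        u=cohort.bmi_percentile.copy(),
        alive=np.ones(n, dtype=bool),
        onset=np.full((n, nd), -1, dtype=np.int16),
        death_year=np.full(n, -1, dtype=np.int16),
        band=band_of_age(cohort.age),
        z=np.empty(n),
    )
    state.z = compiled.standard_quantile(state.band, state.sex, state.u)

    # Optional prevalent disease at entry (cycle 0).
    if compiled.prevalence0.any():
        prev_p = compiled.prevalence0[:, state.band, state.sex].T
        prev_p = np.where(compiled.applicable[:, state.sex].T, prev_p, 0.0)
        seeded = rng.uniform(size=(n, nd)) < prev_p
        state.onset[seeded] = 0

    incident = np.zeros((T, nd), dtype=np.int64)
    deaths = np.zeros(T, dtype=np.int64)
    alive_end = np.zeros(T, dtype=np.int64)
    for t in range(1, T + 1):
        tally = annual_cycle(state, t, float(delta[t - 1]), compiled, rng, config.bmi_floor)
        incident[t - 1] = tally["incident"]
        deaths[t - 1] = tally["deaths"]
        alive_end[t - 1] = tally["alive_end"]

    trace = SimulationTrace(
        disease_ids=list(compiled.disease_ids),
        onset_year=state.onset,
        death_year=state.death_year,
        sex=np.asarray(cohort.sex, dtype=np.int8),
        horizon=T,
    )
    tables = _cost_utility_from_compiled(compiled)
    economics = econ.accumulate_economics(trace, profile, tables, config)

    cases = incident.sum(axis=0)
    summary = pd.DataFrame(
        {
            "disease": compiled.disease_ids,
            "cases": cases,
            "mean": [summarize_incidence(int(c), n)[0] for c in cases],
            "variance": [summarize_incidence(int(c), n)[1] for c in cases],
        }
    ).set_index("disease")

    return SimulationResult(
        scenario=profile.name if profile is not None else "baseline",
        config=config,
        n=n,
        incident_cases=pd.DataFrame(
            incident, index=pd.RangeIndex(1, T + 1, name="year"), columns=compiled.disease_ids
        ),
        deaths_by_year=deaths,
        alive_by_year=alive_end,
        economics=economics,
        incidence_summary=summary,
        trace=trace if config.keep_trace else None,
    )


def _cost_utility_from_compiled(compiled: CompiledEpi) -> econ.CostUtilityTable:
    frame = pd.DataFrame(
        {
            "annual_cost": compiled.annual_cost,
            "utility_male": np.exp(compiled.log_utility[:, 0]),
            "utility_female": np.exp(compiled.log_utility[:, 1]),
        },
        index=compiled.disease_ids,
    )
    return econ.CostUtilityTable(frame)
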