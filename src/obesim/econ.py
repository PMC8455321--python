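"""Costs, utilities, QALYs and discounting.

Conventions (all configurable only where noted):

* Discounting: the first model year is undiscounted and year ``t`` carries
  the factor ``(1 + r)^-(t-1)`` — costs and benefits *beyond* the first
  year are discounted, at 1.5% per annum by default.
* Utility: 1 with no obesity-related disease, 0 when dead, and the product
  of per-disease multipliers under multimorbidity (diseases treated as
  independent).
* Disease costs are chronic: the annual per-case cost accrues every year
  from onset until death.
* No half-cycle correction: an individual who dies in a cycle contributes
  neither costs nor utility for that cycle.
* Currency is 2016 GBP throughout; no internal inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .epi import DiseaseDefinition, InputError, SEXES
from .trajectories import TrajectorySpec, annual_delta_series

if TYPE_CHECKING:  # pragma: no cover
    from .microsim import SimulationConfig, SimulationTrace


def discount_factor(year_index: int, rate: float) -> float:
    """Discount factor for model year ``year_index`` (1-based); DF(1) = 1."""
    if year_index < 1:
        raise InputError(f"year_index must be >= 1, got {year_index}")
    return (1.0 + rate) ** (-(year_index - 1))


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    """Vector of DF(1..horizon)."""
    t = np.arange(1, horizon + 1)
    return (1.0 + rate) ** (-(t - 1.0))


# ---------------------------------------------------------------------------
# Cost / utility table


@dataclass
class CostUtilityTable:
    """Per-disease annual treatment cost (GBP/case/year) and utility multiplier by sex."""

    frame: pd.DataFrame  # index: disease id; columns: annual_cost, utility_male, utility_female

    @classmethod
    def from_diseases(cls, diseases: Iterable[DiseaseDefinition]) -> "CostUtilityTable":
        rows = {
            d.id: {
                "annual_cost": d.annual_cost,
                "utility_male": d.utility.get("male", float("nan")),
                "utility_female": d.utility.get("female", float("nan")),
            }
            for d in diseases
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    def validate(self) -> list[str]:
        errs = []
        for did, row in self.frame.iterrows():
            if row["annual_cost"] < 0:
                errs.append(f"cost table: annual_cost < 0 for {did}")
            for col in ("utility_male", "utility_female"):
                u = row[col]
                if np.isfinite(u) and not 0.0 <= u <= 1.0:
                    errs.append(f"cost table: {col}={u} outside [0,1] for {did}")
        return errs

    def utility(self, disease_id: str, sex: str) -> float:
        if disease_id not in self.frame.index:
            raise InputError(f"unknown disease id {disease_id!r} in cost/utility table")
        return float(self.frame.loc[disease_id, f"utility_{sex}"])

    def annual_cost(self, disease_id: str) -> float:
        if disease_id not in self.frame.index:
            raise InputError(f"unknown disease id {disease_id!r} in cost/utility table")
        return float(self.frame.loc[disease_id, "annual_cost"])

    def arrays(self, disease_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(cost[d], log_utility[d, sex]) aligned to ``disease_ids``.

        A NaN utility (sex to which the disease does not apply) contributes
        a log-multiplier of 0, i.e. no decrement.
        """
        missing = [d for d in disease_ids if d not in self.frame.index]
        if missing:
            raise InputError(f"diseases missing from cost/utility table: {missing}")
        sub = self.frame.loc[disease_ids]
        cost = sub["annual_cost"].to_numpy(float)
        logu = np.zeros((len(disease_ids), 2))
        for s_idx, sex in enumerate(SEXES):
            u = sub[f"utility_{sex}"].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                lu = np.log(u)
            logu[:, s_idx] = np.where(np.isfinite(lu), lu, 0.0)
        return cost, logu


def annual_utility(
    diseases: Iterable[str], sex: str, table: CostUtilityTable, alive: bool = True
) -> float:
    """Utility for one person-year: 0 dead, 1 disease-free, else the product."""
    if not alive:
        return 0.0
    u = 1.0
    for d in diseases:
        m = table.utility(d, sex)
        if np.isfinite(m):
            u *= m
    return u


# ---------------------------------------------------------------------------
# Intervention profile


@dataclass
class InterventionProfile:
    """An intervention's per-person delivery-cost schedule and BMI trajectory.

    The schedule is a frame of rows ``(year_start, year_end, annual_cost)``
    in GBP/person/year; years not covered by any row cost zero, which
    encodes both finite programmes and open-ended annual tails (a single
    row spanning many years).
    """

    name: str
    schedule: pd.DataFrame  # columns: year_start, year_end, annual_cost
    trajectory: TrajectorySpec | None = None

    def __post_init__(self) -> None:
        if (self.schedule["annual_cost"] < 0).any():
            raise InputError(f"profile {self.name!r}: negative delivery cost")
        if (self.schedule["year_start"] > self.schedule["year_end"]).any():
            raise InputError(f"profile {self.name!r}: year_start > year_end")

    def delivery_costs(self, horizon: int) -> np.ndarray:
        """Per-person delivery cost for years 1..horizon."""
        out = np.zeros(horizon)
        for _, row in self.schedule.iterrows():
            lo = int(row["year_start"]) - 1
            hi = min(int(row["year_end"]), horizon)
            out[lo:hi] += row["annual_cost"]
        return out

    def annual_delta(self, horizon: int) -> np.ndarray:
        """ΔBMI for years 1..horizon (zeros when no trajectory attached)."""
        if self.trajectory is None:
            return np.zeros(horizon)
        spec = self.trajectory
        if spec.horizon != horizon:
            spec = TrajectorySpec(
                name=spec.name,
                observed_points=list(spec.observed_points),
                regain_rule=spec.regain_rule,
                horizon=horizon,
            )
        return annual_delta_series(spec)


#: The do-nothing comparator: no delivery costs, no BMI shift.
def baseline_profile() -> InterventionProfile:
    return InterventionProfile(
        name="baseline",
        schedule=pd.DataFrame(columns=["year_start", "year_end", "annual_cost"]).astype(
            {"year_start": int, "year_end": int, "annual_cost": float}
        ),
    )


def total_delivery_cost(
    profile: InterventionProfile,
    horizon: int,
    rate: float = 0.015,
    discounted: bool = False,
) -> float:
    """Per-person delivery cost over the horizon, plain or discounted sum."""
    costs = profile.delivery_costs(horizon)
    if not discounted:
        return float(costs.sum())
    return float(costs @ discount_factors(horizon, rate))


# ---------------------------------------------------------------------------
# Accumulation over a simulation trace


@dataclass
class EconomicsResult:
    """Discounted economic flows of one scenario run (GBP, QALYs)."""

    n: int
    horizon: int
    discount_rate: float
    intervention_cost_by_year: np.ndarray  # discounted, total over cohort
    disease_cost_by_year: np.ndarray
    qalys_by_year: np.ndarray
    person_years_by_year: np.ndarray  # discounted person-years alive

    @property
    def intervention_cost(self) -> float:
        return float(self.intervention_cost_by_year.sum())

    @property
    def disease_cost(self) -> float:
        return float(self.disease_cost_by_year.sum())

    @property
    def total_cost(self) -> float:
        return self.intervention_cost + self.disease_cost

    @property
    def qalys(self) -> float:
        return float(self.qalys_by_year.sum())

    @property
    def person_years(self) -> float:
        return float(self.person_years_by_year.sum())

    def per_100k(self, value: float) -> float:
        return value * 100_000.0 / self.n

    @property
    def intervention_cost_per_100k(self) -> float:
        return self.per_100k(self.intervention_cost)

    @property
    def disease_cost_per_100k(self) -> float:
        return self.per_100k(self.disease_cost)

    @property
    def total_cost_per_100k(self) -> float:
        return self.per_100k(self.total_cost)

    @property
    def qalys_per_100k(self) -> float:
        return self.per_100k(self.qalys)


def accumulate_economics(
    trace: "SimulationTrace",
    profile: InterventionProfile | None,
    tables: CostUtilityTable,
    config: "SimulationConfig",
) -> EconomicsResult:
    """Discounted intervention costs, disease costs and QALYs from a trace.

    For each cycle ``t`` only individuals alive through the cycle
    (``death_year > t`` or never dying) accrue flows; a disease contributes
    from its onset cycle onwards.
    """
    T = trace.horizon
    n = trace.n
    df = discount_factors(T, config.discount_rate)
    cost_vec, logu = tables.arrays(trace.disease_ids)
    delivery = (
        profile.delivery_costs(T) if profile is not None else np.zeros(T)
    )

    death = trace.death_year
    onset = trace.onset_year
    sex = trace.sex
    logu_i = logu[:, sex].T  # (n, d) log utility per individual per disease

    int_cost = np.zeros(T)
    dis_cost = np.zeros(T)
    qalys = np.zeros(T)
    pyrs = np.zeros(T)
    for t in range(1, T + 1):
        alive = (death < 0) | (death > t)
        present = (onset >= 0) & (onset <= t) & alive[:, None]
        dis_cost[t - 1] = df[t - 1] * float((present @ cost_vec).sum())
        utility = np.exp((present * logu_i).sum(axis=1))
        qalys[t - 1] = df[t - 1] * float(utility[alive].sum())
        n_alive = int(alive.sum())
        pyrs[t - 1] = df[t - 1] * n_alive
        int_cost[t - 1] = df[t - 1] * delivery[t - 1] * n_alive
    return EconomicsResult(
        n=n,
        horizon=T,
        discount_rate=config.discount_rate,
        intervention_cost_by_year=int_cost,
        disease_cost_by_year=dis_cost,
        qalys_by_year=qalys,
        person_years_by_year=pyrs,
    )
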