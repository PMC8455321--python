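"""CSV schemas, packaged reference tables and input validation.

All tabular I/O is UTF-8 CSV with a header row.  An epidemiological
parameter set is a directory of eight files:

========================  =====================================================
population.csv            age_band, sex, proportion
bmi_distribution.csv      age_band, sex, excess_shape, excess_scale
bmi_trend.csv             age_band, sex, logit_drift
mortality.csv             age_band, sex, annual_prob
diseases.csv              disease, name, sexes, annual_cost, utility_male,
                          utility_female, rr_tracks_fatality
incidence.csv             disease, age_band, sex, annual_prob
                          [, initial_prevalence]
relative_risks.csv        disease, age_band, bmi_category, rr
case_fatality.csv         disease, age_band, sex, annual_prob
========================  =====================================================

Trajectories: ``intervention, time_years, delta_bmi``.  Delivery-cost
schedules: ``intervention, year_start, year_end, annual_cost`` (a row
spanning many years encodes an open-ended annual tail).

The package also ships reference tables transcribed from the published
economic model: the per-year intervention delivery-cost schedules, the
disease cost/utility table, and the published cost-effectiveness totals
with their printed dominance labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import ScenarioSummary
from .econ import CostUtilityTable, InterventionProfile
from .epi import DiseaseDefinition, EpiParameterSet, InputError

EPI_FILES = {
    "population": "population.csv",
    "bmi_distribution": "bmi_distribution.csv",
    "bmi_trend": "bmi_trend.csv",
    "mortality": "mortality.csv",
    "diseases": "diseases.csv",
    "incidence": "incidence.csv",
    "relative_risks": "relative_risks.csv",
    "case_fatality": "case_fatality.csv",
}

#: Display names for the modelled interventions.
INTERVENTION_NAMES = {
    "baseline": "Baseline",
    "wmp1": "WMP1",
    "vlcd_wmp1": "VLCD added to WMP1",
    "wmp2": "WMP2",
    "look_ahead": "Look AHEAD",
    "rygb": "RYGB Surgery",
}


def _data_path(name: str):
    return importlib.resources.files("obesim.data").joinpath(name)


# ---------------------------------------------------------------------------
# Epi parameter sets


def write_epi_tables(epi: EpiParameterSet, directory: str | Path) -> None:
    """Write a parameter set to its eight-file CSV directory schema."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    epi.population.to_csv(directory / EPI_FILES["population"], index=False)
    epi.bmi_distribution.to_csv(directory / EPI_FILES["bmi_distribution"], index=False)
    epi.bmi_trend.to_csv(directory / EPI_FILES["bmi_trend"], index=False)
    epi.all_cause_mortality.to_csv(directory / EPI_FILES["mortality"], index=False)

    meta, inc, rr, fat = [], [], [], []
    for d in epi.diseases:
        meta.append(
            {
                "disease": d.id,
                "name": d.name,
                "sexes": d.sexes,
                "annual_cost": d.annual_cost,
                "utility_male": d.utility.get("male", np.nan),
                "utility_female": d.utility.get("female", np.nan),
                "rr_tracks_fatality": d.rr_tracks_fatality,
            }
        )
        inc.append(d.incidence.assign(disease=d.id))
        rr.append(d.rr_by_bmi.assign(disease=d.id))
        fat.append(d.case_fatality.assign(disease=d.id))
    pd.DataFrame(meta).to_csv(directory / EPI_FILES["diseases"], index=False)
    pd.concat(inc, ignore_index=True).to_csv(directory / EPI_FILES["incidence"], index=False)
    pd.concat(rr, ignore_index=True).to_csv(directory / EPI_FILES["relative_risks"], index=False)
    pd.concat(fat, ignore_index=True).to_csv(directory / EPI_FILES["case_fatality"], index=False)


def read_epi_tables(directory: str | Path) -> EpiParameterSet:
    """Read and validate a parameter-set directory; raises on schema violations."""
    directory = Path(directory)
    frames = {}
    for key, fname in EPI_FILES.items():
        path = directory / fname
        if not path.exists():
            raise InputError(f"missing parameter table {path}")
        frames[key] = pd.read_csv(path)

    meta = frames["diseases"]
    diseases = []
    for _, row in meta.iterrows():
        did = row["disease"]
        diseases.append(
            DiseaseDefinition(
                id=did,
                name=row.get("name", did),
                incidence=frames["incidence"][frames["incidence"]["disease"] == did].drop(columns="disease"),
                rr_by_bmi=frames["relative_risks"][frames["relative_risks"]["disease"] == did].drop(columns="disease"),
                case_fatality=frames["case_fatality"][frames["case_fatality"]["disease"] == did].drop(columns="disease"),
                annual_cost=float(row["annual_cost"]),
                utility={"male": float(row["utility_male"]), "female": float(row["utility_female"])},
                sexes=row["sexes"],
                rr_tracks_fatality=bool(row["rr_tracks_fatality"]),
            )
        )
    return EpiParameterSet(
        population=frames["population"],
        bmi_distribution=frames["bmi_distribution"],
        bmi_trend=frames["bmi_trend"],
        all_cause_mortality=frames["mortality"],
        diseases=diseases,
    ).require_valid()


# ---------------------------------------------------------------------------
# Trajectories and delivery costs


def read_trajectories(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read observed BMI-change points per intervention from CSV."""
    df = pd.read_csv(path)
    required = {"intervention", "time_years", "delta_bmi"}
    if not required <= set(df.columns):
        raise InputError(f"trajectory file {path}: expected columns {sorted(required)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for name, grp in df.groupby("intervention"):
        grp = grp.sort_values("time_years")
        out[str(name)] = list(zip(grp["time_years"].astype(float), grp["delta_bmi"].astype(float)))
    return out


def write_trajectories(points: dict[str, list[tuple[float, float]]], path: str | Path) -> None:
    rows = [
        {"intervention": name, "time_years": t, "delta_bmi": v}
        for name, pts in points.items()
        for t, v in pts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cost_schedules(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-intervention delivery-cost schedules from CSV."""
    df = pd.read_csv(path)
    required = {"intervention", "year_start", "year_end", "annual_cost"}
    if not required <= set(df.columns):
        raise InputError(f"cost schedule {path}: expected columns {sorted(required)}")
    return {
        str(name): grp.drop(columns="intervention").reset_index(drop=True)
        for name, grp in df.groupby("intervention")
    }


def load_delivery_cost_schedules() -> dict[str, pd.DataFrame]:
    """The packaged per-year intervention delivery-cost schedules (GBP/person)."""
    with importlib.resources.as_file(_data_path("intervention_costs.csv")) as p:
        return read_cost_schedules(p)


def load_cost_utility_table() -> CostUtilityTable:
    """The packaged disease cost/utility table (2016 GBP, EQ-5D multipliers)."""
    with importlib.resources.as_file(_data_path("disease_costs_utilities.csv")) as p:
        df = pd.read_csv(p).set_index("disease")
    return CostUtilityTable(df[["annual_cost", "utility_male", "utility_female"]])


def load_published_results(block: str = "base_case") -> tuple[list[ScenarioSummary], pd.DataFrame]:
    """Published cost-effectiveness totals and printed dominance labels.

    ``block`` is ``base_case`` (five-year regain) or ``regain_sensitivity``
    (fitted-trend regain).  Returns the rows as :class:`ScenarioSummary`
    (costs in £m/100k, QALYs/100k, as printed) together with the raw frame,
    which keeps the printed incremental cells and labels — these carry the
    source's display rounding and are stored verbatim rather than
    reconciled with values recomputed from the totals.
    """
    with importlib.resources.as_file(_data_path("published_results.csv")) as p:
        df = pd.read_csv(p)
    blocks = set(df["block"])
    if block not in blocks:
        raise InputError(f"unknown results block {block!r}; expected one of {sorted(blocks)}")
    sub = df[df["block"] == block].reset_index(drop=True)
    summaries = [
        ScenarioSummary(
            name=row["name"],
            intervention_cost=float(row["intervention_cost"]),
            disease_cost=float(row["disease_cost"]),
            total_cost=float(row["total_cost"]),
            total_qalys=float(row["total_qalys"]),
        )
        for _, row in sub.iterrows()
    ]
    return summaries, sub


def build_profiles(
    schedules: dict[str, pd.DataFrame],
    trajectories: dict[str, "object"],
) -> dict[str, InterventionProfile]:
    """Join cost schedules with trajectory specs into intervention profiles."""
    profiles = {}
    for name, spec in trajectories.items():
        if name not in schedules:
            raise InputError(f"no delivery-cost schedule for intervention {name!r}")
        profiles[name] = InterventionProfile(name=name, schedule=schedules[name], trajectory=spec)
    return profiles


# ---------------------------------------------------------------------------
# Validation report


@dataclass
class FileReport:
    path: str
    ok: bool
    messages: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    entries: list[FileReport] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(e.ok for e in self.entries)

    def add(self, path: str | Path, messages: list[str]) -> None:
        self.entries.append(FileReport(str(path), not messages, messages))

    def summary(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(f"{'PASS' if e.ok else 'FAIL'}  {e.path}")
            lines.extend(f"       {m}" for m in e.messages)
        return "\n".join(lines)


def validate_inputs(
    epi_dir: str | Path | None = None,
    trajectories_path: str | Path | None = None,
    costs_path: str | Path | None = None,
) -> ValidationReport:
    """Validate input files without mutating them; per-file diagnostics."""
    report = ValidationReport()
    if epi_dir is not None:
        try:
            epi = read_epi_tables(epi_dir)
            report.add(epi_dir, epi.validate())
        except InputError as exc:
            report.add(epi_dir, [str(exc)])
    if trajectories_path is not None:
        msgs = []
        try:
            pts = read_trajectories(trajectories_path)
            for name, p in pts.items():
                times = [t for t, _ in p]
                if any(b <= a for a, b in zip(times, times[1:])):
                    msgs.append(f"intervention {name!r}: times not strictly increasing")
                if len(p) < 2:
                    msgs.append(f"intervention {name!r}: fewer than 2 observed points")
        except (InputError, FileNotFoundError) as exc:
            msgs.append(str(exc))
        report.add(trajectories_path, msgs)
    if costs_path is not None:
        msgs = []
        try:
            scheds = read_cost_schedules(costs_path)
            for name, df in scheds.items():
                bad = df[df["annual_cost"] < 0]
                for idx in bad.index:
                    msgs.append(f"intervention {name!r}: negative annual_cost at row {idx}")
        except (InputError, FileNotFoundError) as exc:
            msgs.append(str(exc))
        report.add(costs_path, msgs)
    return report
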