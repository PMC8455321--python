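"""End-to-end orchestration: config, scenario runs, outputs, manifest.

A single flat YAML config drives a full run; command-line flags override
config values (flags take precedence).  Outputs per run:

* ``totals.csv``       — one row per scenario of headline discounted totals
* ``per_year.csv``     — one row per scenario x year x disease
* ``frontier.csv``     — the fully incremental frontier
* ``manifest.yaml``    — seed, config hash, package version
* ``run.log``          — per-cycle alive counts and cumulative incidence
* ``summary.png``      — cumulative incident cases avoided per scenario

Re-running with the same manifest (same config + seed) reproduces the CSV
outputs bit-identically.  By default each scenario consumes an independent
seed stream derived from the master seed and the scenario name; with
``common_random_numbers`` enabled, all scenarios share one stream, which
removes Monte-Carlo noise from incremental comparisons.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synth
from .cea import FrontierTable, ScenarioSummary, incremental_frontier
from .cohort import Cohort, sample_cohort
from .econ import InterventionProfile, baseline_profile
from .epi import EpiParameterSet, InputError
from .microsim import SimulationConfig, SimulationResult, run_simulation
from .trajectories import TrajectorySpec

logger = logging.getLogger("obesim")

DEFAULT_SCENARIOS = ["wmp1", "vlcd_wmp1", "wmp2", "look_ahead", "rygb"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full end-to-end run."""

    seed: int = 1
    cohort_size: int = 100_000
    entry_year: int = 2016
    horizon_years: int = 30
    discount_rate: float = 0.015
    regain_rule: str = "five_year"
    common_random_numbers: bool = False
    bmi_floor: float = 15.0
    scenarios: list[str] = field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    #: "generate" (synthetic tables from epi_seed) or a parameter directory path.
    epi_source: str = "generate"
    epi_seed: int = 7
    n_diseases: int = 12
    severity: float = 1.0
    #: "synthetic-demo" or a trajectory CSV path.
    trajectories: str = "synthetic-demo"
    #: "packaged" (published delivery-cost schedules) or a CSV path.
    intervention_costs: str = "packaged"
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def scenario_seed(self, name: str) -> int:
        """Per-scenario seed stream (< 2^31); shared when CRN is enabled."""
        if self.common_random_numbers:
            return self.seed
        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            start_year=self.entry_year,
            horizon_years=self.horizon_years,
            discount_rate=self.discount_rate,
            seed=seed,
            cohort_size=self.cohort_size,
            regain_rule=self.regain_rule,
            bmi_floor=self.bmi_floor,
        )


@dataclass
class RunBundle:
    """In-memory results of one end-to-end run."""

    config: RunConfig
    results: dict[str, SimulationResult]
    frontier: FrontierTable
    manifest: dict


def load_epi(config: RunConfig) -> EpiParameterSet:
    if config.epi_source == "generate":
        return synth.generate_epi_tables(
            seed=config.epi_seed, n_diseases=config.n_diseases, severity=config.severity
        )
    return io.read_epi_tables(config.epi_source)


def load_profiles(config: RunConfig) -> dict[str, InterventionProfile]:
    """Resolve cost schedules + trajectories into the configured scenario profiles."""
    if config.intervention_costs == "packaged":
        schedules = io.load_delivery_cost_schedules()
    else:
        schedules = io.read_cost_schedules(config.intervention_costs)
    if config.trajectories == "synthetic-demo":
        specs = synth.demo_trajectories(
            horizon=config.horizon_years, regain_rule=config.regain_rule
        )
    else:
        points = io.read_trajectories(config.trajectories)
        specs = {
            name: TrajectorySpec(
                name=name,
                observed_points=pts,
                regain_rule=("surgical_extrapolation" if name == "rygb" else config.regain_rule),
                horizon=config.horizon_years,
            )
            for name, pts in points.items()
        }
    missing = [s for s in config.scenarios if s not in specs]
    if missing:
        raise InputError(
            f"scenario(s) {missing} have no trajectory in {config.trajectories!r}; "
            f"known interventions: {sorted(specs)}"
        )
    no_costs = [s for s in config.scenarios if s not in schedules]
    if no_costs:
        raise InputError(
            f"scenario(s) {no_costs} have no delivery-cost schedule in "
            f"{config.intervention_costs!r}; known interventions: {sorted(schedules)}"
        )
    return {s: InterventionProfile(name=s, schedule=schedules[s], trajectory=specs[s]) for s in config.scenarios}


def run_end_to_end(config: RunConfig, write_outputs: bool = True) -> RunBundle:
    """Validate, simulate every scenario plus baseline, and rank the frontier."""
    epi = load_epi(config)  # validates on construction/read
    profiles = load_profiles(config)
    compiled = epi.compile(config.horizon_years)
    cohort = sample_cohort(epi, config.cohort_size, seed=config.scenario_seed("__cohort__") ^ 0x5EED)

    results: dict[str, SimulationResult] = {}
    sim_cfg = config.simulation_config(config.scenario_seed("baseline"))
    results["baseline"] = run_simulation(sim_cfg, cohort, None, compiled)
    logger.info("scenario baseline: %d cumulative cases", results["baseline"].total_cases)
    for name in config.scenarios:
        sim_cfg = config.simulation_config(config.scenario_seed(name))
        results[name] = run_simulation(sim_cfg, cohort, profiles[name], compiled)
        logger.info("scenario %s: %d cumulative cases", name, results[name].total_cases)
    summaries = [ScenarioSummary.from_simulation(r) for r in results.values()]
    frontier = incremental_frontier(summaries, baseline="baseline")
    manifest = {
        "package": "obesim",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": yaml.safe_load(config.to_yaml()),
    }
    bundle = RunBundle(config=config, results=results, frontier=frontier, manifest=manifest)
    if write_outputs:
        _write_outputs(bundle)
    return bundle


def _write_outputs(bundle: RunBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        # Per-cycle audit trail: alive counts and cumulative incidence.
        log_path = out / "run.log"
        lines = [f"obesim run seed={bundle.config.seed} config_hash={bundle.manifest['config_hash']}"]
        for name, res in bundle.results.items():
            for year, alive, cum in zip(
                res.incident_cases.index,
                res.alive_by_year,
                res.incident_cases.sum(axis=1).cumsum(),
            ):
                lines.append(
                    f"scenario={name} year={year} alive={alive} cumulative_incidence={cum}"
                )
        log_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(log_path)

        totals = pd.concat([r.totals_frame() for r in bundle.results.values()], ignore_index=True)
        p = out / "totals.csv"
        totals.to_csv(p, index=False)
        written.append(p)

        per_year = pd.concat(
            [
                r.incident_cases.reset_index()
                .melt(id_vars="year", var_name="disease", value_name="incident_cases")
                .assign(scenario=name)
                for name, r in bundle.results.items()
            ],
            ignore_index=True,
        )
        p = out / "per_year.csv"
        per_year.to_csv(p, index=False)
        written.append(p)

        p = out / "frontier.csv"
        bundle.frontier.display().to_csv(p, index=False)
        written.append(p)

        p = out / "manifest.yaml"
        p.write_text(yaml.safe_dump(bundle.manifest, sort_keys=True), encoding="utf-8")
        written.append(p)

        _summary_figure(bundle, out / "summary.png")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _summary_figure(bundle: RunBundle, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = bundle.results["baseline"].incident_cases.sum(axis=1).cumsum()
    per100k = bundle.results["baseline"].per_100k
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in bundle.results.items():
        if name == "baseline":
            continue
        avoided = (base - res.incident_cases.sum(axis=1).cumsum()) * per100k
        ax.plot(res.incident_cases.index, avoided, label=io.INTERVENTION_NAMES.get(name, name))
    ax.set_xlabel("Model year")
    ax.set_ylabel("Cumulative cases avoided per 100,000")
    ax.set_title("Obesity-related disease avoided vs baseline")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
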