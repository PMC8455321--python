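"""Cost-effectiveness analysis: pairwise ICERs and the incremental frontier.

An ICER is the difference in total costs divided by the difference in
QALYs between two options.  The fully incremental analysis ranks options
in ascending order of total cost and excludes:

* *dominated* options — more costly and less effective than some
  alternative (weak dominance: no cheaper-or-equal option with at least as
  many QALYs and a strict difference in one coordinate);
* *extendedly dominated* options — excluded because another option
  delivers greater QALY gains at a lower ICER.  Implemented as the
  standard iterative rule: while the ICERs along the surviving cost-ranked
  sequence are not strictly increasing, remove the option whose ICER
  against its predecessor is at least that of its successor against it.

The surviving set is exactly the lower convex hull of the (QALY, cost)
scatter, which the test-suite verifies against an independent hull oracle.

Costs are carried in £m per 100,000 population and QALYs per 100,000, the
scale the economics layer reports; ICERs are returned in £ per QALY.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epi import InputError

#: Scale factor from "£m per 100k" cost differences to £.
_MILLION = 1e6

NONDOMINATED = "nondominated"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class ScenarioSummary:
    """Headline discounted totals of one scenario, per 100,000 population."""

    name: str
    intervention_cost: float  # £m / 100k
    disease_cost: float  # £m / 100k
    total_cost: float  # £m / 100k
    total_qalys: float  # QALYs / 100k

    @classmethod
    def from_simulation(cls, result) -> "ScenarioSummary":
        e = result.economics
        return cls(
            name=result.scenario,
            intervention_cost=e.intervention_cost_per_100k / _MILLION,
            disease_cost=e.disease_cost_per_100k / _MILLION,
            total_cost=e.total_cost_per_100k / _MILLION,
            total_qalys=e.qalys_per_100k,
        )


def pairwise_icer(a: ScenarioSummary, baseline: ScenarioSummary) -> float:
    """ICER of ``a`` against ``baseline`` in £ per QALY.

    Negative values arise when one option is cheaper but less effective (or
    costlier but more effective is the usual positive case); a zero QALY
    difference leaves the ratio undefined and returns NaN.
    """
    dq = a.total_qalys - baseline.total_qalys
    if dq == 0:
        return float("nan")
    dc = (a.total_cost - baseline.total_cost) * _MILLION
    return dc / dq


def offset_fraction(intervention: ScenarioSummary, baseline: ScenarioSummary) -> float:
    """Percent of delivery cost offset by savings on obesity-related disease."""
    if intervention.intervention_cost <= 0:
        raise InputError(
            f"{intervention.name!r} has no delivery cost; offset fraction undefined"
        )
    return (
        100.0
        * (baseline.disease_cost - intervention.disease_cost)
        / intervention.intervention_cost
    )


@dataclass
class FrontierTable:
    """Scenarios ranked by cost with dominance labels and ICERs.

    ``frame`` columns: name, intervention_cost, disease_cost, total_cost,
    total_qalys, status, icer_vs_next (against the next non-dominated,
    less-effective option; NaN off the frontier and for the cheapest row),
    icer_vs_baseline.
    """

    frame: pd.DataFrame
    baseline: str

    @property
    def nondominated(self) -> list[str]:
        return list(self.frame.loc[self.frame["status"] == NONDOMINATED, "name"])

    def status_of(self, name: str) -> str:
        row = self.frame[self.frame["name"] == name]
        if row.empty:
            raise InputError(f"unknown scenario {name!r}")
        return str(row["status"].iloc[0])

    def display(self) -> pd.DataFrame:
        """Human-readable view: ICERs rounded to whole £, dominance spelt out.

        A negative ICER against baseline where the option is both cheaper
        and more effective is printed as ``Dominant``.
        """
        out = self.frame.copy()
        base = out[out["name"] == self.baseline].iloc[0]

        def _fmt(row, col):
            v = row[col]
            if row["status"] == DOMINATED:
                return "Dominated"
            if row["status"] == EXT_DOMINATED:
                return "Ext Dom"
            if not np.isfinite(v):
                return "-"
            if (
                col == "icer_vs_baseline"
                and row["total_cost"] < base["total_cost"]
                and row["total_qalys"] > base["total_qalys"]
            ):
                return "Dominant"
            return f"£{v:,.0f}"

        for col in ("icer_vs_next", "icer_vs_baseline"):
            out[col + "_display"] = out.apply(lambda r: _fmt(r, col), axis=1)
        return out


def incremental_frontier(
    scenarios: list[ScenarioSummary], baseline: str | None = None
) -> FrontierTable:
    """Fully incremental analysis of two or more scenarios.

    ``baseline`` names the comparator for the ``icer_vs_baseline`` column;
    by default the least costly scenario.  Frontier membership itself never
    depends on which row is called baseline.
    """
    if len(scenarios) < 2:
        raise InputError("need at least 2 scenarios including a baseline")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise InputError(f"duplicate scenario names: {dupes}")

    order = sorted(range(len(scenarios)), key=lambda i: (scenarios[i].total_cost, -scenarios[i].total_qalys))
    rows = [scenarios[i] for i in order]
    cost = np.array([s.total_cost for s in rows])
    qaly = np.array([s.total_qalys for s in rows])
    n = len(rows)
    status = [NONDOMINATED] * n

    # Weak dominance.
    for j, i in itertools.product(range(n), range(n)):
        if i == j or status[j] != NONDOMINATED:
            continue
        if (
            cost[i] <= cost[j]
            and qaly[i] >= qaly[j]
            and (cost[i] < cost[j] or qaly[i] > qaly[j])
        ):
            status[j] = DOMINATED

    # Extended dominance: enforce strictly increasing ICERs along the rank.
    while True:
        active = [i for i in range(n) if status[i] == NONDOMINATED]
        if len(active) < 3:
            break
        icers = [
            (cost[b] - cost[a]) * _MILLION / (qaly[b] - qaly[a])
            for a, b in zip(active, active[1:])
        ]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                status[active[k + 1]] = EXT_DOMINATED
                removed = True
                break
        if not removed:
            break

    active = [i for i in range(n) if status[i] == NONDOMINATED]
    icer_next = np.full(n, np.nan)
    for a, b in zip(active, active[1:]):
        icer_next[b] = (cost[b] - cost[a]) * _MILLION / (qaly[b] - qaly[a])

    if baseline is None:
        base_idx = 0
    else:
        try:
            base_idx = next(i for i, s in enumerate(rows) if s.name == baseline)
        except StopIteration:
            raise InputError(f"baseline scenario {baseline!r} not among the inputs") from None
    icer_base = np.array(
        [
            pairwise_icer(s, rows[base_idx]) if i != base_idx else np.nan
            for i, s in enumerate(rows)
        ]
    )

    frame = pd.DataFrame(
        {
            "name": [s.name for s in rows],
            "intervention_cost": [s.intervention_cost for s in rows],
            "disease_cost": [s.disease_cost for s in rows],
            "total_cost": cost,
            "total_qalys": qaly,
            "status": status,
            "icer_vs_next": icer_next,
            "icer_vs_baseline": icer_base,
        }
    )
    return FrontierTable(frame=frame, baseline=rows[base_idx].name)


def sensitivity_sweep(
    runner,
    discount_rates,
    horizons,
    regain_rules,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Frontier outcomes over a discount-rate x horizon x regain-rule grid.

    ``runner(discount_rate, horizon, regain_rule)`` must return the list of
    :class:`ScenarioSummary` for that cell (typically by re-running the
    simulation).  Returns the concatenated frontier frames with grid
    columns attached; identical cells give identical outputs.
    """
    frames = []
    for rate, horizon, rule in itertools.product(discount_rates, horizons, regain_rules):
        summaries = runner(discount_rate=rate, horizon=horizon, regain_rule=rule)
        ft = incremental_frontier(summaries, baseline=baseline)
        frames.append(
            ft.frame.assign(discount_rate=rate, horizon=horizon, regain_rule=rule)
        )
    return pd.concat(frames, ignore_index=True)
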