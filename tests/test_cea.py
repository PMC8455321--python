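"""ICERs, dominance, the incremental frontier and sensitivity sweeps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from obesim import io
from obesim.cea import (
    DOMINATED,
    EXT_DOMINATED,
    NONDOMINATED,
    ScenarioSummary,
    incremental_frontier,
    offset_fraction,
    pairwise_icer,
    sensitivity_sweep,
)
from obesim.epi import InputError


def _s(name, cost, qalys, int_cost=0.0):
    return ScenarioSummary(
        name=name,
        intervention_cost=int_cost,
        disease_cost=cost - int_cost,
        total_cost=cost,
        total_qalys=qalys,
    )


# ---------------------------------------------------------------------------
# pairwise ICERs


def test_adding_vlcd_to_wmp1_costs_about_121k_per_qaly():
    """From the published totals: (3032-2909) £m over (1,155,963-1,154,944)
    QALYs is ~£121,000 per QALY gained."""
    base_case, _ = io.load_published_results("base_case")
    by_name = {s.name: s for s in base_case}
    icer = pairwise_icer(by_name["vlcd_wmp1"], by_name["wmp1"])
    assert icer == pytest.approx(123e6 / 1019, rel=1e-12)
    assert icer == pytest.approx(121_000, rel=0.02)


def test_equal_cost_more_qalys_gives_zero_icer():
    assert pairwise_icer(_s("a", 100.0, 2000.0), _s("b", 100.0, 1000.0)) == 0.0


def test_zero_qaly_difference_is_undefined():
    assert np.isnan(pairwise_icer(_s("a", 120.0, 1000.0), _s("b", 100.0, 1000.0)))


# ---------------------------------------------------------------------------
# dominance frontier


def test_published_base_case_dominance_structure():
    """From the printed base-case totals: VLCD added to WMP1 is dominated
    (WMP2 is cheaper and more effective) and Look AHEAD is extendedly
    dominated; baseline, WMP1 and RYGB survive with strictly increasing
    ICERs and RYGB's frontier ICER lands on ~£11.6k/QALY vs WMP1."""
    scenarios, _ = io.load_published_results("base_case")
    table = incremental_frontier(scenarios, baseline="baseline")
    assert table.status_of("vlcd_wmp1") == DOMINATED
    assert table.status_of("look_ahead") == EXT_DOMINATED
    for name in ("baseline", "wmp1", "rygb"):
        assert table.status_of(name) == NONDOMINATED
    active = table.frame[table.frame["status"] == NONDOMINATED]
    icers = active["icer_vs_next"].dropna().to_numpy()
    assert np.all(np.diff(icers) > 0)
    # RYGB vs its non-dominated predecessor, from unrounded differences
    rygb = table.frame.set_index("name").loc["rygb"]
    assert rygb["icer_vs_baseline"] == pytest.approx((4319 - 2898) * 1e6 / 140362, rel=1e-9)


def test_published_sensitivity_block_labels_reproduced_exactly():
    """The fitted-trend sensitivity block is arithmetically self-consistent:
    recomputing dominance from its printed totals reproduces every printed
    label (baseline itself dominated, WMP2 dominant, Look AHEAD ext. dom.)."""
    scenarios, printed = io.load_published_results("regain_sensitivity")
    table = incremental_frontier(scenarios, baseline="baseline")
    for _, row in printed.iterrows():
        assert table.status_of(row["name"]) == row["printed_status"], row["name"]
    # WMP2 saves money and gains QALYs vs baseline: displayed as Dominant
    disp = table.display().set_index("name")
    assert disp.loc["wmp2", "icer_vs_baseline_display"] == "Dominant"


def test_two_scenarios_reduce_to_the_pairwise_icer():
    a, b = _s("base", 100.0, 1000.0), _s("tx", 150.0, 1010.0)
    table = incremental_frontier([a, b])
    assert table.frame.set_index("name").loc["tx", "icer_vs_next"] == pytest.approx(
        pairwise_icer(b, a)
    )


def test_duplicate_names_rejected():
    with pytest.raises(InputError):
        incremental_frontier([_s("a", 1.0, 10.0), _s("a", 2.0, 20.0)])


def test_scale_invariance_of_icers():
    rng = np.random.default_rng(5)
    scen = [_s(f"s{i}", float(c), float(q)) for i, (c, q) in enumerate(zip(rng.uniform(1, 10, 5), rng.uniform(100, 200, 5)))]
    t1 = incremental_frontier(scen)
    k = 7.5
    scaled = [_s(s.name, s.total_cost * k, s.total_qalys) for s in scen]
    t2 = incremental_frontier(scaled)
    assert list(t1.frame["status"]) == list(t2.frame["status"])
    np.testing.assert_allclose(
        t2.frame["icer_vs_next"].to_numpy(float),
        t1.frame["icer_vs_next"].to_numpy(float) * k,
        rtol=1e-9,
        equal_nan=True,
    )


def _hull_oracle(scenarios):
    """Independent frontier oracle: dominance filter, then the lower convex
    hull of (QALY, cost) by brute-force slope check."""
    pts = [(s.total_qalys, s.total_cost, s.name) for s in scenarios]
    nondom = [
        p
        for p in pts
        if not any(
            (o[1] <= p[1] and o[0] >= p[0] and (o[1] < p[1] or o[0] > p[0]))
            for o in pts
            if o is not p
        )
    ]
    nondom.sort()
    hull = []
    for p in nondom:
        while len(hull) >= 2:
            (q1, c1, _), (q2, c2, _) = hull[-2], hull[-1]
            q3, c3, _ = p
            # pop while the middle point lies on or above the chord
            if (c2 - c1) * (q3 - q1) >= (c3 - c1) * (q2 - q1):
                hull.pop()
            else:
                break
        hull.append(p)
    return {name for _, _, name in hull}


def test_frontier_agrees_with_convex_hull_oracle_on_random_instances():
    """On 1000 random 6-scenario sets the iterative dominance algorithm and
    the brute-force lower-hull oracle select identical frontiers."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        scen = [
            _s(f"s{i}", float(c), float(q))
            for i, (c, q) in enumerate(
                zip(rng.uniform(0, 5000, 6), rng.uniform(1.0e6, 1.3e6, 6))
            )
        ]
        table = incremental_frontier(scen)
        assert set(table.nondominated) == _hull_oracle(scen)


# ---------------------------------------------------------------------------
# offset fraction


def test_surgery_offset_fraction_about_30_percent():
    """Published totals: disease-cost savings offset ~30% of the RYGB
    delivery cost — 100 x (2898-2295)/2024 = 29.8%."""
    scenarios, _ = io.load_published_results("base_case")
    by_name = {s.name: s for s in scenarios}
    offset = offset_fraction(by_name["rygb"], by_name["baseline"])
    assert offset == pytest.approx(100 * (2898 - 2295) / 2024, rel=1e-12)
    assert offset == pytest.approx(30.0, abs=1.0)


def test_offset_fraction_edge_cases():
    base = _s("base", 2898.0, 1.0)
    same = ScenarioSummary("tx", 100.0, base.disease_cost, 100.0 + base.disease_cost, 2.0)
    assert offset_fraction(same, base) == 0.0
    full = ScenarioSummary("tx2", 100.0, base.disease_cost - 100.0, base.disease_cost, 2.0)
    assert offset_fraction(full, base) == pytest.approx(100.0)
    with pytest.raises(InputError):
        offset_fraction(base, base)


# ---------------------------------------------------------------------------
# sensitivity sweeps


def _stream_runner(discount_rate, horizon, regain_rule):
    """Deterministic scenario summaries from fixed cost/QALY streams.

    The costly option front-loads its cost and back-loads its QALYs, the
    structure under which discounting matters most.
    """
    df = (1.0 + discount_rate) ** -(np.arange(1, horizon + 1) - 1.0)
    base_q = np.full(horizon, 1000.0)
    cheap_cost = np.zeros(horizon)
    costly_cost = np.zeros(horizon)
    costly_cost[0] = 2000.0
    gain = np.linspace(0.0, 12.0, horizon)  # QALY gains arrive late
    return [
        _s("baseline", float(cheap_cost @ df), float(base_q @ df)),
        _s("costly", float(costly_cost @ df), float((base_q + gain) @ df), int_cost=float(costly_cost @ df)),
    ]


def test_lower_discount_rates_favour_back_loaded_benefits():
    table = sensitivity_sweep(_stream_runner, [0.0, 0.035], [30], ["five_year"])
    icers = table.set_index(["discount_rate", "name"])["icer_vs_next"]
    assert icers.loc[(0.0, "costly")] < icers.loc[(0.035, "costly")]


def test_sweep_is_deterministic_and_truncates_with_horizon():
    t1 = sensitivity_sweep(_stream_runner, [0.015], [10, 30], ["five_year"])
    t2 = sensitivity_sweep(_stream_runner, [0.015], [10, 30], ["five_year"])
    pd.testing.assert_frame_equal(t1, t2)
    q = t1.set_index(["horizon", "name"])["total_qalys"]
    gain10 = q.loc[(10, "costly")] - q.loc[(10, "baseline")]
    gain30 = q.loc[(30, "costly")] - q.loc[(30, "baseline")]
    assert gain10 < gain30
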