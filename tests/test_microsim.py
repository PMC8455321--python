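"""Engine behaviour: incidence arithmetic, cycle dynamics, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from obesim.cohort import sample_cohort
from obesim.econ import InterventionProfile
from obesim.epi import InputError
from obesim.microsim import (
    SimulationConfig,
    incidence_probability,
    run_simulation,
    summarize_incidence,
)
from obesim.trajectories import TrajectorySpec
from conftest import make_flat_epi


# ---------------------------------------------------------------------------
# incidence probability and binomial summaries


def test_incidence_probability_multiplies_base_by_rr():
    epi = make_flat_epi([{"id": "d1", "p_inc": 0.01, "rr": [1, 1, 1, 2, 2.5]}])
    d = epi.diseases[0]
    assert incidence_probability(d, age=50, sex="male", bmi=20.0) == pytest.approx(0.01)
    assert incidence_probability(d, age=50, sex="male", bmi=42.0) == pytest.approx(0.025)


def test_incidence_probability_caps_at_one_and_validates():
    epi = make_flat_epi([{"id": "d1", "p_inc": 0.6, "rr": [1, 1, 1, 2, 2]}])
    d = epi.diseases[0]
    assert incidence_probability(d, age=50, sex="male", bmi=42.0) == 1.0
    with pytest.raises(InputError):
        incidence_probability(d, age=50, sex="male", bmi=0.0)


@pytest.mark.parametrize(
    "cases, n, mean, var",
    [(10, 100, 0.1, 0.1 * 0.9 / 100), (0, 50, 0.0, 0.0), (50, 50, 1.0, 0.0)],
)
def test_binomial_incidence_summary(cases, n, mean, var):
    m, v = summarize_incidence(cases, n)
    assert m == pytest.approx(mean)
    assert v == pytest.approx(var)


def test_binomial_summary_validates_inputs():
    with pytest.raises(InputError):
        summarize_incidence(5, 0)
    with pytest.raises(InputError):
        summarize_incidence(11, 10)


# ---------------------------------------------------------------------------
# cycle dynamics


def _run_flat(epi, n=2_000, seed=1, horizon=10, profile=None, keep_trace=False):
    cohort = sample_cohort(epi, n, seed=seed)
    cfg = SimulationConfig(
        seed=seed + 1, cohort_size=n, horizon_years=horizon, keep_trace=keep_trace
    )
    return run_simulation(cfg, cohort, profile, epi)


def test_null_dynamics_change_nothing_but_age():
    epi = make_flat_epi([{"id": "d1", "p_inc": 0.0}], mortality=0.0)
    res = _run_flat(epi)
    assert res.total_cases == 0
    assert res.deaths_by_year.sum() == 0
    assert np.all(res.alive_by_year == 2_000)


def test_certain_death_is_absorbing():
    epi = make_flat_epi([{"id": "d1", "p_inc": 0.1}], mortality=1.0)
    res = _run_flat(epi)
    assert res.deaths_by_year[0] == 2_000
    assert np.all(res.deaths_by_year[1:] == 0)
    assert np.all(res.alive_by_year == 0)
    assert res.incident_cases.iloc[1:].to_numpy().sum() == 0  # no tallies for the dead


def test_constant_hazard_matches_geometric_survival():
    """One disease, constant annual probability p, no mortality: cumulative
    incidence over T years follows N(1 - (1-p)^T), a closed form."""
    p, T, n = 0.05, 10, 20_000
    epi = make_flat_epi([{"id": "d1", "p_inc": p}], mortality=0.0)
    res = _run_flat(epi, n=n, seed=3, horizon=T)
    q = 1.0 - (1.0 - p) ** T
    expected = n * q
    sd = np.sqrt(n * q * (1 - q))
    assert abs(res.total_cases - expected) < 3 * sd


def test_simulation_is_bit_reproducible(epi_small, cohort_small):
    cfg = SimulationConfig(seed=17, cohort_size=cohort_small.size)
    a = run_simulation(cfg, cohort_small, None, epi_small)
    b = run_simulation(cfg, cohort_small, None, epi_small)
    pd.testing.assert_frame_equal(a.incident_cases, b.incident_cases)
    np.testing.assert_array_equal(a.deaths_by_year, b.deaths_by_year)
    assert a.economics.qalys == b.economics.qalys
    assert a.economics.total_cost == b.economics.total_cost


def test_lower_bmi_path_reduces_incidence_as_a_trend():
    """A uniformly lower BMI path yields stochastically fewer cumulative
    cases; checked as a trend across 20 seed pairs."""
    epi = make_flat_epi(
        [{"id": "d1", "p_inc": 0.02, "rr": [1.0, 1.3, 1.7, 2.2, 2.8]}], mortality=0.01
    )
    shift = TrajectorySpec(
        name="shift",
        observed_points=[(0, -3.0), (30, -3.0)],
        regain_rule="fitted_trend",
        horizon=30,
    )
    schedule = pd.DataFrame({"year_start": [], "year_end": [], "annual_cost": []})
    profile = InterventionProfile(name="shift", schedule=schedule, trajectory=shift)
    diffs = []
    for seed in range(20):
        cohort = sample_cohort(epi, 1_500, seed=seed)
        cfg = SimulationConfig(seed=seed, cohort_size=1_500)
        base = run_simulation(cfg, cohort, None, epi)
        low = run_simulation(cfg, cohort, profile, epi)
        diffs.append(low.total_cases - base.total_cases)
    diffs = np.asarray(diffs)
    assert diffs.mean() < 0
    assert (diffs < 0).sum() >= 15


def test_rr_tracking_fatality_raises_mortality():
    """Flagging a disease's fatality to follow its incidence RR (the
    poor-survival-cancer convention) increases deaths relative to the
    unflagged disease, all else equal."""
    spec = {"id": "d1", "p_inc": 0.05, "p_fat": 0.05, "rr": [1, 2, 3, 4, 5]}
    plain = make_flat_epi([dict(spec)])
    tracked = make_flat_epi([dict(spec, rr_tracks_fatality=True)])
    d_plain = _run_flat(plain, n=5_000, seed=9, horizon=15).deaths_by_year.sum()
    d_tracked = _run_flat(tracked, n=5_000, seed=9, horizon=15).deaths_by_year.sum()
    assert d_tracked > d_plain


# ---------------------------------------------------------------------------
# Markov-recursion oracle


def _markov_oracle(p1, p2, f1, f2, q_all, T):
    """Deterministic cohort-level recursion for two diseases with constant
    rates.  States: (has d1, has d2) for the living, plus dead.  Returns
    per-year expected prevalence of each disease among the initial cohort
    (fraction), expected deaths per year, and expected incident cases.
    """
    probs = {(0, 0): 1.0, (1, 0): 0.0, (0, 1): 0.0, (1, 1): 0.0}
    dead = 0.0
    prev1, prev2, deaths, inc1, inc2 = [], [], [], [], []
    for _ in range(T):
        new = {s: 0.0 for s in probs}
        i1 = probs[(0, 0)] * p1 + probs[(0, 1)] * p1
        i2 = probs[(0, 0)] * p2 + probs[(1, 0)] * p2
        inc1.append(i1)
        inc2.append(i2)
        # incidence transitions
        new[(0, 0)] += probs[(0, 0)] * (1 - p1) * (1 - p2)
        new[(1, 0)] += probs[(0, 0)] * p1 * (1 - p2) + probs[(1, 0)] * (1 - p2)
        new[(0, 1)] += probs[(0, 0)] * (1 - p1) * p2 + probs[(0, 1)] * (1 - p1)
        new[(1, 1)] += (
            probs[(0, 0)] * p1 * p2
            + probs[(1, 0)] * p2
            + probs[(0, 1)] * p1
            + probs[(1, 1)]
        )
        # death after incidence
        d_year = 0.0
        for (h1, h2), mass in new.items():
            q = 1 - (1 - q_all) * (1 - f1) ** h1 * (1 - f2) ** h2
            d_year += mass * q
            new[(h1, h2)] = mass * (1 - q)
        dead += d_year
        probs = new
        deaths.append(d_year)
        prev1.append(probs[(1, 0)] + probs[(1, 1)])
        prev2.append(probs[(0, 1)] + probs[(1, 1)])
    return map(np.asarray, (prev1, prev2, deaths, inc1, inc2))


def test_microsimulation_matches_markov_recursion():
    """On a constant-rate two-disease state space the stochastic engine must
    agree with the deterministic Markov recursion within 3 Monte-Carlo SDs
    at N = 100,000, year by year."""
    p1, p2, f1, f2, q_all, T, n = 0.03, 0.05, 0.02, 0.01, 0.01, 15, 100_000
    epi = make_flat_epi(
        [
            {"id": "d1", "p_inc": p1, "p_fat": f1},
            {"id": "d2", "p_inc": p2, "p_fat": f2},
        ],
        mortality=q_all,
    )
    res = _run_flat(epi, n=n, seed=0, horizon=T, keep_trace=True)
    prev1, prev2, deaths, inc1, inc2 = _markov_oracle(p1, p2, f1, f2, q_all, T)

    onset = res.trace.onset_year
    death = res.trace.death_year
    for t in range(1, T + 1):
        alive = (death < 0) | (death > t)
        for k, prev in ((0, prev1), (1, prev2)):
            have = ((onset[:, k] >= 0) & (onset[:, k] <= t) & alive).sum()
            exp = n * prev[t - 1]
            sd = np.sqrt(n * prev[t - 1] * (1 - prev[t - 1]))
            assert abs(have - exp) <= 3 * sd + 1e-9, f"disease {k+1} prevalence, year {t}"
        d_obs = res.deaths_by_year[t - 1]
        sd = np.sqrt(n * deaths[t - 1] * (1 - deaths[t - 1]))
        assert abs(d_obs - n * deaths[t - 1]) <= 3 * sd + 1e-9, f"deaths, year {t}"
    for k, inc in ((0, inc1), (1, inc2)):
        cases = res.incident_cases.iloc[:, k].sum()
        exp = n * inc.sum()
        sd = np.sqrt(n * inc.sum())  # Poisson-scale bound on the cumulative count
        assert abs(cases - exp) <= 3 * sd
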