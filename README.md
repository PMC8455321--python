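# obesim

Microsimulation decision model for the cost-effectiveness of weight-management
interventions in adults with severe obesity (BMI ≥ 35 kg/m²).

`obesim` is aimed at health-economics analysts who need an individual-level,
30-year decision model rather than a within-trial analysis. It simulates a
closed virtual cohort through annual cycles: each person ages, follows a
counterfactual BMI trajectory, stochastically acquires obesity-related
disease as a function of age, sex and BMI, and may die from all-cause or
disease-specific mortality. Interventions (behavioural weight-management
programmes of increasing intensity, a very-low-calorie diet add-on, and
gastric-bypass surgery) shift the BMI trajectory and carry per-year delivery
costs; the economics layer turns the simulated histories into discounted
costs and QALYs and the CEA layer into pairwise ICERs and a fully
incremental dominance frontier.

## The model in brief

* **Cohort.** A closed cohort (members leave only through death) sampled by
  5-year age band × sex, with BMI ≥ 35 kg/m² guaranteed by construction
  (BMI = 35 + Gamma-distributed excess per stratum). Each individual keeps a
  fixed BMI percentile; their counterfactual BMI in later years is the same
  percentile mapped through the stratum's projected distribution
  (quantile mapping), with secular drift parameterised on the logit scale of
  the top-category (≥ 40) share.
* **Disease incidence.** Semi-Markov annual cycles: each absent disease *d*
  occurs with probability
  `p = min(I_d(age, sex) · RR_d(age band, BMI category), 1)`,
  persists for life once acquired, and contributes an annual case-fatality
  hazard. Death combines hazards on the probability scale:
  `q = 1 − (1 − q_allcause) · Π_d (1 − q_d)`.
* **Trajectories.** Sparse trial ΔBMI observations are linearly interpolated
  to an annual grid and extended by a regain rule: linear return to baseline
  over five years (base case), an OLS trend fitted to the observations
  (sensitivity), or linear extrapolation of the last observed segment
  (surgery, which has 20-year follow-up). ΔBMI shifts every individual's
  counterfactual BMI additively, floored at 15 kg/m².
* **Economics.** Utility is 1 when disease-free, 0 when dead, and the
  product of per-disease multipliers under multimorbidity; disease costs are
  chronic per-case annual costs from onset to death; the first year is
  undiscounted and year *t* carries `(1 + r)^−(t−1)` (r = 1.5 %/year).
* **CEA.** `ICER = ΔC / ΔQ`. The fully incremental analysis ranks options by
  total cost, removes dominated options (costlier and less effective), then
  iteratively removes extendedly dominated options until ICERs strictly
  increase — the surviving set is the lower convex hull of the (QALY, cost)
  scatter.

Real national epidemiology (BMI distributions, life tables, per-disease
incidence and relative risks) is an external input supplied as CSV tables;
the package ships a synthetic generator (`obesim.synth`) that emulates their
statistical structure with known ground truth, plus the published per-year
intervention delivery-cost schedules, disease cost/utility table and
scenario totals as packaged reference data.

## Worked example

Ranking the published base-case scenario totals (costs in £m per 100,000
population, QALYs per 100,000):

```python
from obesim import io
from obesim.cea import incremental_frontier, pairwise_icer

scenarios, _ = io.load_published_results("base_case")
table = incremental_frontier(scenarios, baseline="baseline")
print(table.display()[["name", "total_cost", "total_qalys", "status",
                       "icer_vs_next_display"]].to_string(index=False))
```

```
      name  total_cost  total_qalys               status icer_vs_next_display
  baseline      2898.0    1135676.0         nondominated                    -
      wmp1      2909.0    1154944.0         nondominated                 £571
      wmp2      2933.0    1158386.0         nondominated               £6,973
 vlcd_wmp1      3032.0    1155963.0            dominated            Dominated
look_ahead      3643.0    1167101.0 extendedly_dominated              Ext Dom
      rygb      4319.0    1276038.0         nondominated              £11,781
```

VLCD added to WMP1 is dominated (WMP2 delivers more QALYs for less money)
and Look AHEAD is extendedly dominated; surgery buys the largest QALY gain
at a frontier ICER near £11.7k per QALY. Adding the VLCD to WMP1 instead of
comparing against baseline is poor value:

```python
by = {s.name: s for s in scenarios}
pairwise_icer(by["vlcd_wmp1"], by["wmp1"])   # 120707.56 £/QALY
```

A full synthetic end-to-end run (generates epidemiology, simulates baseline
plus five interventions, writes totals, per-year counts, the frontier, a
manifest and a summary figure):

```bash
obesim simulate --seed 1 --cohort-size 20000 --crn --out results/demo
```

```
      name  intervention_cost  disease_cost  total_cost  total_qalys        status  icer_vs_next_display
  baseline               0.00       1766.11     1766.11    1007911.0  nondominated                     -
      ...
      rygb            1633.97       1483.27     3117.24    1143662.0  nondominated                £9,953
```

Here the synthetic world's frontier keeps only baseline and surgery: the
modest BMI shifts of the behavioural programmes are positive but, at this
cohort size, their QALY gains are bought at a higher ICER than surgery's.
`--crn` shares one random stream across scenarios so incremental
comparisons are not swamped by Monte-Carlo noise. `obesim sweep` repeats
the analysis over a discount-rate × horizon × regain-rule grid, and
`obesim generate-inputs` / `obesim validate` round-trip the parameter-table
schemas.

## Layout

```
src/obesim/
  epi.py           strata, BMI-excess distributions, parameter containers
  synth.py         synthetic epidemiology + trial generator (ground truth)
  cohort.py        cohort sampling, quantile-mapped BMI projection
  trajectories.py  interpolation, regain rules, weight→BMI conversion
  microsim.py      the annual-cycle Monte-Carlo engine
  econ.py          discounting, utilities, costs, accumulation
  cea.py           ICERs, dominance frontier, sensitivity sweeps
  runner.py / cli.py  configuration, orchestration, `obesim` CLI
  data/            packaged delivery-cost, cost/utility and results tables
docs/methods.md    modelling assumptions, conventions and limitations
```
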