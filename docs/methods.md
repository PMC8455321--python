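# Methods

This note documents the modelling choices behind `obesim`: the simulation
procedure and its assumptions, the parameters that matter, what the
synthetic-data generator does and does not emulate, the numerical
conventions, and known limitations.

## Model structure

The unit of simulation is an individual in a closed cohort entering at the
start of 2016 with BMI ≥ 35 kg/m². Each annual cycle proceeds in a fixed
event order:

1. **Age and BMI update.** Age advances one year (capped in an open-ended
   85+ band, the usual life-table convention). The counterfactual BMI is
   the individual's fixed entry percentile mapped through the current
   year's projected BMI distribution for their age band and sex, plus the
   scenario's ΔBMI for that year, floored at 15 kg/m².
2. **Incidence.** Every absent, sex-applicable disease occurs with
   probability `min(I(age band, sex) · RR(age band, BMI category), 1)`.
   The RR applies to the annual probability, not the hazard; with annual
   probabilities of at most a few percent the distinction is second-order,
   and the cap keeps the product a probability.
3. **Death.** All-cause and per-disease case-fatality risks combine as
   independent on the probability scale:
   `q = 1 − (1 − q_allcause) · Π_d (1 − q_d)`. A disease acquired earlier
   in the same cycle already contributes its fatality. A disease flagged
   `rr_tracks_fatality` multiplies its case fatality by the same BMI RR as
   its incidence — the convention for a cancer whose survival is so poor
   that developing it and dying of it are nearly the same event.
4. **Tallies.** Incident cases, deaths and alive counts are recorded.

Diseases never remit (semi-Markov persistence) and death is absorbing.
Incidence is placed before death within the cycle so that a disease can
occur, remain, or kill in the same framework; no half-cycle correction is
applied anywhere — a person who dies in a cycle contributes no costs,
utility or delivery cost for that cycle.

The engine draws the full individual × disease uniform matrix every cycle
regardless of state. This costs a few megabytes of random numbers per
cycle and buys exact stream alignment: two scenarios run with the same
seed consume randomness identically, so a shared seed acts as common
random numbers (CRN) and a scenario with ΔBMI ≡ 0 reproduces the baseline
run draw for draw. CRN is off by default (independent per-scenario streams
derived from the master seed and the scenario name) and enabled with
`common_random_numbers` / `--crn`.

## BMI distribution and projection

Within each age-band × sex stratum, BMI is `35 + X` with
`X ~ Gamma(shape, scale)` — the entry criterion holds exactly and the right
tail is realistic. Secular change is a single per-stratum parameter: an
annual drift, on the logit scale, of the proportion of the stratum above
40 kg/m². The year-*t* distribution keeps the entry shape and re-solves the
scale so its upper tail matches the drifted share, which has the closed
form `scale(t) = 5 / Q⁻¹(shape, p_t)` with `Q⁻¹` the inverse regularised
upper incomplete gamma. Zero drift is special-cased to the identity, so
the no-trend scenario is bit-exact.

Individual paths use quantile mapping: the percentile is fixed at entry
and evaluated in the projected stratum distribution each year. This is a
modelling decision, not an estimated quantity — it is the minimal rule
that reproduces the projected category proportions while giving each
individual a coherent, monotone path (a higher-percentile individual is
heavier in every year). The unit-scale Gamma quantile is cached per
individual and re-solved only when an age-band boundary is crossed.

## Trajectories and regain

Trial ΔBMI observations (time in years since delivery, ΔBMI relative to
trial baseline, drop-out-adjusted upstream, anchored at (0, 0)) are
linearly interpolated to the annual grid; the value at year-end *t* applies
during cycle *t*. Beyond the last observation:

* **five_year** (base case, non-surgical): ΔBMI returns linearly to 0 in
  exactly five annual steps from the final data point, then stays 0.
* **fitted_trend** (sensitivity): an OLS line through all observed points
  is extrapolated, clamped at 0 once it crosses baseline. Regain never
  overshoots above the counterfactual trajectory; whether the source
  analyses clamp here is unstated, so the clamp is our documented choice.
  A flat or downward trend is carried to the horizon.
* **surgical_extrapolation**: the line through the last two observed points
  continues to the horizon (clamped at 0), reflecting that surgery has
  20-year follow-up and only the final decade needs extrapolating; the
  regain-rule sensitivity switch deliberately does not touch surgery.

ΔBMI is applied additively — the same absolute shift for every individual —
because the trials report population-mean BMI change; the 15 kg/m² floor
guards degenerate combinations. Weight changes reported in kg convert to
ΔBMI via `Δkg / height²` with sex-adjusted mean heights (1.75 m male,
1.62 m female by default, configurable).

## Economics

* Discounting: DF(1) = 1 and DF(t) = (1 + r)^−(t−1), r = 1.5 %/year by
  default — costs and benefits *beyond the first year* are discounted.
* Utility: 1 disease-free, 0 dead, multiplicative across diseases
  (independence assumption). The packaged table carries one value per sex;
  knee osteoarthritis is the sex-specific row (0.49 male / 0.46 female).
* Disease costs are chronic: the per-case annual cost accrues every year
  from onset until death. Whether the source engine accrues for life or
  per episode is unstated; chronic accrual is our documented default.
* Delivery costs follow per-year schedules (GBP/person/year, 2016 GBP, no
  internal inflation); a schedule row spanning years encodes open-ended
  tails such as surgery's annual follow-up from year 11. Delivery cost in
  cycle *t* accrues to individuals alive through cycle *t*.
* All totals are reported per 100,000 population (× 100000/N), making the
  cohort size a precision knob rather than a scale assumption.

## CEA layer

ICER = ΔC/ΔQ in £ per QALY (costs held in £m per 100k, QALYs per 100k).
The incremental frontier sorts by total cost (ties broken by higher
QALYs), removes weakly dominated options, then iteratively removes the
option whose ICER against its predecessor is ≥ the ICER of its successor
against it, until ICERs strictly increase. This is the standard extended
dominance algorithm; the test-suite proves it equivalent to a brute-force
lower-convex-hull oracle on 1000 random instances. A zero QALY difference
leaves an ICER undefined (NaN); display formatting rounds to whole pounds
and prints "Dominant" for options that are cheaper *and* more effective
than the named baseline.

One reconciliation note on the packaged published totals: in the base-case
block the printed totals are rounded to £1m / 1 QALY, and recomputing the
frontier from them leaves WMP2 *on* the frontier (sequential ICERs
571 → 6973 → 11781), whereas the source — computed from unrounded values —
lists WMP2 as extendedly dominated. The fitted-trend sensitivity block is
arithmetically self-consistent and its printed labels are reproduced
exactly. The loader therefore stores printed labels and printed
incremental cells verbatim alongside the totals rather than reconciling
them, and the tests assert the arithmetically derivable structure
(VLCD-added-to-WMP1 dominated, Look AHEAD extendedly dominated,
{baseline, WMP1, RYGB} on the frontier, strictly increasing ICERs).

## Synthetic inputs

The generator emulates the *structure* of the real inputs, not England's
epidemiology: an age-pyramid population with a near-even sex split;
Gamma BMI excess with mean excess ≈ 3.5–5 kg/m²; Gompertz-like all-cause
mortality (non-decreasing in age, lower for women); per-disease incidence
rising exponentially with age; RRs built from positive per-category
increments (monotone in BMI category by construction) with a mild positive
age gradient; lognormal annual treatment costs; utilities in 0.55–0.95;
a subset of female-only diseases; and one poor-survival cancer flagged
`rr_tracks_fatality`. A single `severity` scalar multiplies baseline
incidence and RR increments; at the default `severity = 1` the baseline
run yields roughly 2 × 10⁵ cumulative incident cases per 100,000 over 30
years — the same order of magnitude as a severely obese national cohort,
intended as a plausibility anchor, not a calibration target.

What passing tests on synthetic data do show: the engine's dynamics agree
with closed-form and deterministic oracles; the economics and CEA
arithmetic is exact; lower BMI paths reduce incidence; parameter recovery
works at realistic noise. What they do not show: that the synthetic rates,
costs or trajectories match any real population — real analyses must
supply their own parameter tables through the documented CSV schemas.

The demo trajectories are synthetic stand-ins with field-plausible shapes
(≈1 BMI-unit loss for a 12-week programme, a larger sustained loss with
partial regain for intensive lifestyle support, a deep ~8–12-unit
sustained loss for gastric bypass); they are not digitised trial values.

## Numerical conventions and problem sizes

* Percentiles are clipped to (1e−12, 1 − 1e−12) before Gamma inversion.
* Population proportions must sum to 1 within 1e−9; RR monotonicity is
  checked with a 1e−12 slack; utilities live in [0, 1].
* Random numbers come from numpy's default PCG64 generator; per-scenario
  seeds are derived via `SeedSequence(master, crc32(name))` and kept below
  2³¹.
* The test-suite and the acceptance script run cohorts of 1,500–100,000:
  oracle-equivalence checks use N = 100,000 on 1–2-disease state spaces
  (seconds per check), behavioural tests use 2,000–20,000, and the
  end-to-end synthetic analysis uses 50,000 individuals × 12 diseases ×
  30 years × 6 scenarios. Per-100k reporting makes these sizes a variance
  choice; the conservation, determinism and doubling-invariance tests pin
  the scaling behaviour.

## Limitations

* Disease risk depends on current BMI only, not BMI history.
* One intervention, delivered once at entry; no sequencing or re-referral.
* No probabilistic sensitivity analysis; parameter uncertainty is explored
  only through the deterministic regain/discount/horizon sweeps.
* No prevalent disease at entry unless the incidence table supplies an
  `initial_prevalence` column (default 0).
* No indirect or productivity costs, and no costs of unrelated disease in
  extended life-years.
* Single-stage diseases only; utilities assume independence across
  comorbidities.
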