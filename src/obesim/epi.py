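"""Epidemiological parameter containers and the BMI distribution machinery.

The model works on a closed adult cohort stratified by 5-year age band and
sex.  Within each stratum the BMI of the severely obese subpopulation is
represented as ``35 + excess`` with a Gamma-distributed excess, so every
simulated BMI is >= 35 kg/m^2 by construction and the distribution has a
realistic right tail.

Secular BMI change is parameterised as an annual drift, on the logit scale,
of the proportion of the stratum in the top BMI category (>= 40 kg/m^2).
The year-``t`` distribution is the entry Gamma with its scale re-solved so
that the upper-tail mass above the 40 kg/m^2 cut equals the drifted share;
with the shape held fixed this inversion has the closed form

    scale(t) = 5 / Q^{-1}(shape, p_t)

where ``Q^{-1}`` is the inverse of the regularised upper incomplete gamma
function and ``p_t = expit(logit(p_0) + drift * t)``.  Individuals keep
their entry BMI percentile and are mapped through the year-specific
quantile function (see :mod:`obesim.cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special as sc


class InputError(ValueError):
    """Raised when user-supplied parameters or tables violate the schema."""


# ---------------------------------------------------------------------------
# Strata

AGE_BAND_LOWER: np.ndarray = np.arange(20, 90, 5)  # 20, 25, ..., 85
AGE_BANDS: tuple[str, ...] = tuple(
    [f"{a}-{a + 4}" for a in range(20, 85, 5)] + ["85+"]
)
N_BANDS: int = len(AGE_BANDS)
SEXES: tuple[str, str] = ("male", "female")

#: Default BMI category cut points (kg/m^2).  The cohort enters at >= 35 so
#: only the top two categories are occupied at entry; the lower categories
#: become reachable after intervention-induced weight loss.
DEFAULT_BMI_CUTS: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)

#: Excess over 35 kg/m^2 at which the top BMI category begins.
TOP_CATEGORY_EXCESS: float = 5.0

#: Lowest BMI an individual can reach after an intervention shift (kg/m^2).
DEFAULT_BMI_FLOOR: float = 15.0


def band_of_age(age: np.ndarray | int) -> np.ndarray | int:
    """Map integer age(s) to 5-year age-band indices, capped at the open 85+ band."""
    idx = (np.asarray(age) - 20) // 5
    return np.clip(idx, 0, N_BANDS - 1).astype(np.intp)


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise InputError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def category_labels(cuts: Sequence[float] = DEFAULT_BMI_CUTS) -> tuple[str, ...]:
    cuts = [float(c) for c in cuts]
    labels = [f"<{cuts[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
    labels.append(f"{cuts[-1]:g}+")
    return tuple(labels)


def bmi_category(bmi: np.ndarray | float, cuts: Sequence[float] = DEFAULT_BMI_CUTS):
    """Category index of a BMI value: 0 = below the first cut, len(cuts) = top."""
    return np.searchsorted(np.asarray(cuts, dtype=float), bmi, side="right")


# ---------------------------------------------------------------------------
# Disease definition


@dataclass
class DiseaseDefinition:
    """One obesity-related disease and everything the engine needs about it.

    ``incidence`` and ``case_fatality`` are annual probabilities by age band
    and sex; ``rr_by_bmi`` gives the relative risk of incidence per age band
    and BMI category (reference category RR = 1, non-decreasing across
    categories).  ``rr_tracks_fatality`` marks a disease whose incidence RR
    also multiplies its case fatality — the convention used for cancers with
    survival so poor that incidence and death risk are interchangeable.
    """

    id: str
    name: str
    incidence: pd.DataFrame  # columns: age_band, sex, annual_prob[, initial_prevalence]
    rr_by_bmi: pd.DataFrame  # columns: age_band, bmi_category, rr
    case_fatality: pd.DataFrame  # columns: age_band, sex, annual_prob
    annual_cost: float
    utility: dict[str, float]
    sexes: str = "both"  # both | female_only | male_only
    rr_tracks_fatality: bool = False

    def applicable_to(self, sex: str) -> bool:
        if self.sexes == "both":
            return True
        return self.sexes == f"{sex}_only"

    def validate(self, cuts: Sequence[float] = DEFAULT_BMI_CUTS) -> list[str]:
        """Return a list of human-readable schema violations (empty if valid)."""
        errs: list[str] = []
        if self.sexes not in ("both", "female_only", "male_only"):
            errs.append(f"disease {self.id}: sexes={self.sexes!r} invalid")
        if self.annual_cost < 0:
            errs.append(f"disease {self.id}: annual_cost negative")
        for sex, u in self.utility.items():
            if np.isfinite(u) and not (0.0 <= u <= 1.0):
                errs.append(f"disease {self.id}: utility[{sex}]={u} outside [0,1]")
        for label, df in (("incidence", self.incidence), ("case_fatality", self.case_fatality)):
            bad = df[(df["annual_prob"] < 0) | (df["annual_prob"] > 1)]
            for _, row in bad.iterrows():
                errs.append(
                    f"disease {self.id}: {label} annual_prob={row['annual_prob']} "
                    f"outside [0,1] at age_band={row['age_band']}, sex={row['sex']}"
                )
        labels = category_labels(cuts)
        rr = self.rr_by_bmi
        for band, grp in rr.groupby("age_band"):
            ordered = grp.set_index("bmi_category").reindex(list(labels))["rr"]
            if ordered.isna().any():
                missing = [l for l in labels if l not in set(grp["bmi_category"])]
                errs.append(f"disease {self.id}: rr_by_bmi missing categories {missing} in band {band}")
                continue
            vals = ordered.to_numpy(float)
            if not np.isclose(vals[0], 1.0):
                errs.append(f"disease {self.id}: reference-category RR is {vals[0]}, must be 1 (band {band})")
            if np.any(np.diff(vals) < -1e-12):
                errs.append(
                    f"disease {self.id}: rr_by_bmi not non-decreasing across BMI "
                    f"categories in band {band} (monotonicity rule)"
                )
        return errs


# ---------------------------------------------------------------------------
# Parameter set


def _pivot_band_sex(df: pd.DataFrame, value: str, fill: float = 0.0) -> np.ndarray:
    """Pivot an (age_band, sex, value) frame to a dense [N_BANDS, 2] array."""
    out = np.full((N_BANDS, 2), fill, dtype=float)
    band_pos = {b: i for i, b in enumerate(AGE_BANDS)}
    for _, row in df.iterrows():
        b, s = row["age_band"], row["sex"]
        if b not in band_pos:
            raise InputError(f"unknown age_band {b!r}; expected one of {AGE_BANDS}")
        out[band_pos[b], sex_index(s)] = row[value]
    return out


@dataclass
class EpiParameterSet:
    """All exogenous epidemiology the simulation consumes.

    Attributes
    ----------
    population
        Proportion of the cohort in each 5-year age band x sex cell
        (columns ``age_band, sex, proportion``; sums to 1).
    bmi_distribution
        Per band x sex: ``excess_shape`` and ``excess_scale`` of the Gamma
        distribution of BMI excess over 35 kg/m^2 at entry.
    bmi_trend
        Per band x sex: ``logit_drift``, the annual drift on the logit scale
        of the proportion of the stratum in the top (>= 40) BMI category.
    all_cause_mortality
        Annual death probability by band x sex (columns
        ``age_band, sex, annual_prob``); non-decreasing in age within sex.
    diseases
        List of :class:`DiseaseDefinition`.
    """

    population: pd.DataFrame
    bmi_distribution: pd.DataFrame
    bmi_trend: pd.DataFrame
    all_cause_mortality: pd.DataFrame
    diseases: list[DiseaseDefinition]
    bmi_category_cuts: tuple[float, ...] = DEFAULT_BMI_CUTS

    def validate(self) -> list[str]:
        errs: list[str] = []
        tot = float(self.population["proportion"].sum())
        if abs(tot - 1.0) > 1e-9:
            errs.append(f"population: proportions sum to {tot!r}, expected 1 +- 1e-9")
        if (self.population["proportion"] < 0).any():
            errs.append("population: negative proportion")
        if (self.bmi_distribution["excess_shape"] <= 0).any() or (
            self.bmi_distribution["excess_scale"] <= 0
        ).any():
            errs.append("bmi_distribution: Gamma shape/scale must be positive")
        mort = self.all_cause_mortality
        bad = mort[(mort["annual_prob"] < 0) | (mort["annual_prob"] > 1)]
        for _, row in bad.iterrows():
            errs.append(
                f"all_cause_mortality: annual_prob={row['annual_prob']} outside "
                f"[0,1] at age_band={row['age_band']}, sex={row['sex']}"
            )
        order = {b: i for i, b in enumerate(AGE_BANDS)}
        for sex, grp in mort.groupby("sex"):
            q = grp.assign(_i=grp["age_band"].map(order)).sort_values("_i")["annual_prob"].to_numpy()
            if np.any(np.diff(q) < -1e-12):
                errs.append(f"all_cause_mortality: not non-decreasing in age for sex={sex}")
        seen: set[str] = set()
        for d in self.diseases:
            if d.id in seen:
                errs.append(f"duplicate disease id {d.id!r}")
            seen.add(d.id)
            errs.extend(d.validate(self.bmi_category_cuts))
        return errs

    def require_valid(self) -> "EpiParameterSet":
        errs = self.validate()
        if errs:
            raise InputError("invalid EpiParameterSet:\n" + "\n".join(errs))
        return self

    def disease(self, disease_id: str) -> DiseaseDefinition:
        for d in self.diseases:
            if d.id == disease_id:
                return d
        raise InputError(f"unknown disease id {disease_id!r}")

    def compile(self, horizon_years: int) -> "CompiledEpi":
        return CompiledEpi.from_parameters(self, horizon_years)


# ---------------------------------------------------------------------------
# Compiled (dense-array) view used by the engine


def _gamma_scale_for_top_share(shape: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Gamma scale such that P(excess > TOP_CATEGORY_EXCESS) = p for given shape."""
    return TOP_CATEGORY_EXCESS / sc.gammainccinv(shape, p)


@dataclass
class CompiledEpi:
    """Dense numpy view of an :class:`EpiParameterSet` for a fixed horizon."""

    cuts: np.ndarray
    horizon: int
    shape: np.ndarray  # [band, sex]
    theta: np.ndarray  # [band, sex, horizon] projected Gamma scale, index t-1 = cycle t
    mortality: np.ndarray  # [band, sex]
    disease_ids: list[str]
    incidence: np.ndarray  # [d, band, sex]
    rr: np.ndarray  # [d, band, n_categories]
    fatality: np.ndarray  # [d, band, sex]
    prevalence0: np.ndarray  # [d, band, sex]
    applicable: np.ndarray  # [d, sex] bool
    rr_tracks_fatality: np.ndarray  # [d] bool
    annual_cost: np.ndarray  # [d]
    log_utility: np.ndarray  # [d, sex] log multipliers (0 where inapplicable)
    population: np.ndarray  # [band, sex]

    @classmethod
    def from_parameters(cls, epi: EpiParameterSet, horizon_years: int) -> "CompiledEpi":
        epi.require_valid()
        cuts = np.asarray(epi.bmi_category_cuts, dtype=float)
        labels = category_labels(cuts)
        ncat = len(labels)

        shape = _pivot_band_sex(epi.bmi_distribution, "excess_shape", fill=np.nan)
        scale0 = _pivot_band_sex(epi.bmi_distribution, "excess_scale", fill=np.nan)
        if np.isnan(shape).any() or np.isnan(scale0).any():
            raise InputError("bmi_distribution: missing age_band x sex cells")
        drift = _pivot_band_sex(epi.bmi_trend, "logit_drift", fill=0.0)

        # Projected Gamma scale per calendar offset.  Drift of zero keeps the
        # entry scale bit-exactly so the no-trend scenario is an identity.
        p0 = sc.gammaincc(shape, TOP_CATEGORY_EXCESS / scale0)
        theta = np.empty((N_BANDS, 2, horizon_years))
        logit_p0 = sc.logit(p0)
        for t in range(horizon_years):
            if t == 0:
                theta[:, :, 0] = scale0
                continue
            pt = sc.expit(logit_p0 + drift * t)
            theta[:, :, t] = np.where(
                drift == 0.0, scale0, _gamma_scale_for_top_share(shape, pt)
            )

        mortality = _pivot_band_sex(epi.all_cause_mortality, "annual_prob")

        nd = len(epi.diseases)
        incidence = np.zeros((nd, N_BANDS, 2))
        rr = np.ones((nd, N_BANDS, ncat))
        fatality = np.zeros((nd, N_BANDS, 2))
        prevalence0 = np.zeros((nd, N_BANDS, 2))
        applicable = np.ones((nd, 2), dtype=bool)
        tracks = np.zeros(nd, dtype=bool)
        cost = np.zeros(nd)
        logu = np.zeros((nd, 2))
        band_pos = {b: i for i, b in enumerate(AGE_BANDS)}
        cat_pos = {c: i for i, c in enumerate(labels)}

        for k, d in enumerate(epi.diseases):
            incidence[k] = _pivot_band_sex(d.incidence, "annual_prob")
            if "initial_prevalence" in d.incidence.columns:
                prevalence0[k] = _pivot_band_sex(d.incidence, "initial_prevalence")
            for _, row in d.rr_by_bmi.iterrows():
                b = band_pos.get(row["age_band"])
                c = cat_pos.get(row["bmi_category"])
                if b is None or c is None:
                    raise InputError(
                        f"disease {d.id}: unknown age_band/bmi_category "
                        f"({row['age_band']!r}, {row['bmi_category']!r})"
                    )
                rr[k, b, c] = row["rr"]
            fatality[k] = _pivot_band_sex(d.case_fatality, "annual_prob")
            if d.sexes == "female_only":
                applicable[k, 0] = False
            elif d.sexes == "male_only":
                applicable[k, 1] = False
            tracks[k] = d.rr_tracks_fatality
            cost[k] = d.annual_cost
            for s_idx, s in enumerate(SEXES):
                u = d.utility.get(s, 1.0)
                logu[k, s_idx] = 0.0 if not np.isfinite(u) else np.log(max(u, 1e-12))

        population = _pivot_band_sex(epi.population, "proportion")
        return cls(
            cuts=cuts,
            horizon=horizon_years,
            shape=shape,
            theta=theta,
            mortality=mortality,
            disease_ids=[d.id for d in epi.diseases],
            incidence=incidence,
            rr=rr,
            fatality=fatality,
            prevalence0=prevalence0,
            applicable=applicable,
            rr_tracks_fatality=tracks,
            annual_cost=cost,
            log_utility=logu,
            population=population,
        )

    # -- BMI quantile machinery -------------------------------------------

    def standard_quantile(self, band, sex, u) -> np.ndarray:
        """Unit-scale Gamma quantile of percentile ``u`` in stratum (band, sex).

        Multiplying by the year-specific scale gives the BMI excess; caching
        this value lets the engine re-solve it only when an individual
        crosses an age-band boundary.
        """
        return sc.gammaincinv(self.shape[band, sex], u)

    def bmi_at(self, band, sex, u, t_index) -> np.ndarray:
        """Counterfactual BMI of percentile ``u`` in stratum (band, sex) at
        calendar offset ``t_index`` (0 = entry year)."""
        z = self.standard_quantile(band, sex, u)
        return 35.0 + self.theta[band, sex, np.minimum(t_index, self.horizon - 1)] * z
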