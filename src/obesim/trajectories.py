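"""Annual BMI-change series: interpolation, regain rules and composition.

Trial weight-change data arrive as sparse (time, ΔBMI) observations
relative to the trial baseline.  This module turns them into a dense annual
series over the model horizon:

* linear interpolation between observed time points;
* beyond the last observation, one of three regain rules:

  - ``five_year``        — linear return of ΔBMI to 0 over exactly five
                           years from the final data point, then 0 (the
                           base-case assumption for non-surgical
                           programmes);
  - ``fitted_trend``     — an OLS line fitted to all observed points and
                           extrapolated, clamped at 0 once it crosses
                           baseline (the sensitivity-analysis assumption);
  - ``surgical_extrapolation`` — the line through the last two observed
                           points continued to the horizon (for surgery,
                           whose long follow-up makes an assumed return to
                           baseline unnecessary), clamped at 0.

ΔBMI is applied additively to each individual's projected counterfactual
BMI — the same absolute population-mean shift for everyone — with a floor
on the resulting BMI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .epi import DEFAULT_BMI_FLOOR, InputError

REGAIN_RULES = ("five_year", "fitted_trend", "surgical_extrapolation")

#: Default sex-adjusted mean adult heights (m) for weight→BMI conversion.
DEFAULT_MEAN_HEIGHTS: dict[str, float] = {"male": 1.75, "female": 1.62}


@dataclass
class TrajectorySpec:
    """An intervention's observed BMI-change points plus its regain rule."""

    name: str
    observed_points: list[tuple[float, float]]
    regain_rule: str = "five_year"
    horizon: int = 30

    def __post_init__(self) -> None:
        if self.regain_rule not in REGAIN_RULES:
            raise InputError(
                f"trajectory {self.name!r}: unknown regain rule "
                f"{self.regain_rule!r}; expected one of {REGAIN_RULES}"
            )
        times = [t for t, _ in self.observed_points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InputError(f"trajectory {self.name!r}: times must be strictly increasing")
        if self.horizon < 1:
            raise InputError(f"trajectory {self.name!r}: horizon must be >= 1")

    def annual_series(self) -> np.ndarray:
        """Dense ΔBMI series for years 1..horizon (index 0 = end of year 1)."""
        return annual_delta_series(self)


def _check_points(points: Sequence[tuple[float, float]], minimum: int = 2) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([p[0] for p in points], dtype=float)
    v = np.asarray([p[1] for p in points], dtype=float)
    if len(t) < minimum:
        raise InputError(f"need at least {minimum} observed points, got {len(t)}")
    if len(np.unique(t)) != len(t):
        raise InputError("duplicate observation times")
    order = np.argsort(t)
    return t[order], v[order]


def interpolate_annual(points: Sequence[tuple[float, float]], horizon: int) -> np.ndarray:
    """Evaluate the piecewise-linear interpolant at years 1..horizon.

    The interpolant passes through every observed point; beyond the last
    observation the last value is held (callers apply a regain rule there).
    """
    t, v = _check_points(points)
    if t.max() > horizon:
        raise InputError(f"observation at {t.max():g} y beyond the {horizon}-year horizon")
    years = np.arange(1, horizon + 1, dtype=float)
    return np.interp(years, t, v)


def apply_regain_five_year(series: np.ndarray, last_data_year: int) -> np.ndarray:
    """Overwrite years after ``last_data_year`` with a 5-year linear return to 0.

    ΔBMI moves from its last observed value to exactly 0 in five equal
    annual steps, then stays at 0 for the rest of the series.
    """
    series = np.asarray(series, dtype=float).copy()
    if not (1 <= last_data_year <= len(series)):
        raise InputError(
            f"last_data_year={last_data_year} outside the series (length {len(series)})"
        )
    last = series[last_data_year - 1]
    for k in range(1, 6):
        idx = last_data_year - 1 + k
        if idx >= len(series):
            break
        series[idx] = last * (1.0 - k / 5.0)
    series[last_data_year + 4 :] = 0.0
    return series


@dataclass
class TrendFit:
    """OLS line ``delta = intercept + slope * t`` with the slope's standard error."""

    slope: float
    intercept: float
    slope_se: float


def fit_trend(points: Sequence[tuple[float, float]]) -> TrendFit:
    """Ordinary least squares through the observed (time, ΔBMI) pairs."""
    t, v = _check_points(points)
    if np.ptp(t) == 0:
        raise InputError("cannot fit a trend: all observation times identical")
    slope, intercept = np.polyfit(t, v, 1)
    n = len(t)
    if n > 2:
        resid = v - (intercept + slope * t)
        sigma2 = float(resid @ resid) / (n - 2)
        sxx = float(((t - t.mean()) ** 2).sum())
        se = math.sqrt(sigma2 / sxx)
    else:
        se = 0.0
    return TrendFit(slope=float(slope), intercept=float(intercept), slope_se=se)


def apply_regain_fitted_trend(
    points: Sequence[tuple[float, float]], horizon: int
) -> np.ndarray:
    """Interpolate within the data, then extrapolate the fitted OLS line.

    The extrapolated segment is clamped at 0 once the line crosses baseline
    (weight regain never overshoots above the counterfactual trajectory).
    A flat or downward trend never returns to baseline and is carried to
    the horizon unchanged.
    """
    series = interpolate_annual(points, horizon)
    t, _ = _check_points(points)
    fit = fit_trend(points)
    years = np.arange(1, horizon + 1, dtype=float)
    beyond = years > t.max()
    series[beyond] = np.minimum(fit.intercept + fit.slope * years[beyond], 0.0)
    return series


def extrapolate_surgical(
    points: Sequence[tuple[float, float]], horizon: int
) -> np.ndarray:
    """Continue the line through the last two observed points to the horizon.

    Intended for surgery, where long follow-up (typically 20 years) exists
    and only the final decade needs extrapolating.  Clamped at 0 should the
    line ever cross baseline.
    """
    t, v = _check_points(points)
    slope = (v[-1] - v[-2]) / (t[-1] - t[-2])
    series = interpolate_annual(points, horizon)
    years = np.arange(1, horizon + 1, dtype=float)
    beyond = years > t.max()
    series[beyond] = np.minimum(v[-1] + slope * (years[beyond] - t[-1]), 0.0)
    return series


def annual_delta_series(spec: TrajectorySpec) -> np.ndarray:
    """Dense annual ΔBMI series (years 1..horizon) under the spec's regain rule."""
    if spec.regain_rule == "fitted_trend":
        return apply_regain_fitted_trend(spec.observed_points, spec.horizon)
    if spec.regain_rule == "surgical_extrapolation":
        return extrapolate_surgical(spec.observed_points, spec.horizon)
    series = interpolate_annual(spec.observed_points, spec.horizon)
    last_time = max(t for t, _ in spec.observed_points)
    last_year = max(1, int(math.ceil(last_time)))
    return apply_regain_five_year(series, min(last_year, spec.horizon))


def weight_to_bmi_delta(
    delta_kg: float, sex: str | None = None, mean_height: float | None = None
) -> float:
    """Convert a weight change (kg) to a BMI change using mean adult height.

    ``ΔBMI = Δkg / height²``.  If ``mean_height`` is not given it is looked
    up from the sex-adjusted defaults (1.75 m male, 1.62 m female).
    """
    if mean_height is None:
        if sex not in DEFAULT_MEAN_HEIGHTS:
            raise InputError(f"sex must be one of {tuple(DEFAULT_MEAN_HEIGHTS)} when mean_height is omitted")
        mean_height = DEFAULT_MEAN_HEIGHTS[sex]
    if mean_height <= 0:
        raise InputError(f"mean_height must be positive, got {mean_height}")
    return delta_kg / mean_height**2


def effective_bmi(baseline_bmi, delta, floor: float = DEFAULT_BMI_FLOOR):
    """Shift the counterfactual BMI by ΔBMI, never below the floor (kg/m^2)."""
    return np.maximum(np.asarray(baseline_bmi, dtype=float) + delta, floor)
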