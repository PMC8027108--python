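"""Parametric survival curves and per-cycle transition probabilities.

The decision model rests on Weibull survival functions

    S(t) = exp(-lambda * t**gamma)

with scale ``lambda`` (units month^(-gamma)) and shape ``gamma``
(dimensionless); ``gamma = 1`` reduces to the exponential model with
constant hazard ``lambda``.  A Markov cycle of length ``u`` months turns
the fitted curve into a per-cycle conditional event probability

    P(t) = 1 - exp[lambda * (t - u)**gamma - lambda * t**gamma]
         = 1 - S(t) / S(t - u),

the probability of an event during the cycle ending at ``t`` given
event-free survival to ``t - u``.

Curves are calibrated either from a printed median (``params_from_median``)
or by least squares on digitized Kaplan-Meier coordinates
(``fit_weibull_to_km``), which exploits the log-log linearisation
``log(-log S) = log(lambda) + gamma * log(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "WeibullParams",
    "KMCurve",
    "CycleSpec",
    "WeibullFit",
    "FitError",
    "weibull_survival",
    "weibull_median",
    "cumulative_event_probability",
    "transition_probability",
    "params_from_median",
    "fit_weibull_to_km",
]

DAYS_PER_MONTH = 365.25 / 12.0


class FitError(RuntimeError):
    """Raised when a Kaplan-Meier curve cannot support a Weibull fit."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair (lambda, gamma) of a Weibull survival curve.

    ``scale`` has units month^(-shape); ``shape`` is dimensionless.
    ``shape == 1`` is the exponential special case with rate ``scale``.
    """

    scale: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")


@dataclass(frozen=True)
class CycleSpec:
    """Model cycle grid: cycle length in days and horizon in years.

    The default 21-day cycle over a 10-year (3,652.5-day) horizon gives
    ``n_cycles = ceil(3652.5 / 21) = 174``.
    """

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * 365.25 / self.cycle_length_days)

    @property
    def cycle_months(self) -> float:
        """Cycle length expressed in months (1 month = 365.25/12 days)."""
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / 365.25


def weibull_survival(params: WeibullParams, t):
    """Survival probability S(t) = exp(-scale * t**shape).

    ``t`` is in months; scalar or array.  Equals 1 at t = 0 and is
    strictly decreasing.  Negative ``t`` raises ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    out = np.exp(-params.scale * np.power(t_arr, params.shape))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def weibull_median(params: WeibullParams) -> float:
    """Time at which survival crosses 0.5: (ln 2 / scale)**(1/shape)."""
    return (math.log(2.0) / params.scale) ** (1.0 / params.shape)


def cumulative_event_probability(rate: float, t: float) -> float:
    """Cumulative event probability P = 1 - exp(-rate * t) at constant rate.

    ``rate`` is per month, ``t`` in months; both must be nonnegative.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if t < 0:
        raise ValueError("time must be nonnegative")
    return -math.expm1(-rate * t)


def transition_probability(params: WeibullParams, t, u: float):
    """Per-cycle conditional event probability for the cycle ending at ``t``.

    Returns ``1 - exp(scale*(t-u)**shape - scale*t**shape)``, i.e.
    ``1 - S(t)/S(t-u)``: the probability of the event during a cycle of
    length ``u`` months given no event by ``t - u``.  Always in [0, 1).
    For ``shape == 1`` the value is independent of ``t`` (memorylessness)
    and equals ``1 - exp(-scale * u)``.
    """
    if u <= 0:
        raise ValueError("cycle length u must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < u):
        raise ValueError("cycle-end time t must be >= cycle length u")
    expo = params.scale * np.power(t_arr - u, params.shape) - params.scale * np.power(
        t_arr, params.shape
    )
    out = -np.expm1(expo)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def params_from_median(median: float, shape: float = 1.0) -> WeibullParams:
    """Calibrate a Weibull curve to a printed median survival time.

    Solves S(median) = 0.5 for the scale at the given shape:
    ``scale = ln 2 / median**shape``.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    return WeibullParams(scale=math.log(2.0) / median**shape, shape=shape)


@dataclass
class KMCurve:
    """Kaplan-Meier coordinates: times (months) and survival probabilities.

    ``survival`` must be nonincreasing and lie in [0, 1]; duplicate time
    points keep the last (lowest) survival value, matching how digitized
    step functions record the post-drop level.  ``at_risk`` counts, when
    present, weight the Weibull fit.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        r = None if self.at_risk is None else np.asarray(self.at_risk, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be 1-d sequences of equal length")
        if r is not None and r.shape != t.shape:
            raise ValueError("at_risk must match times in length")
        if t.size == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        # deduplicate: keep the last entry for each repeated time
        keep = np.append(np.diff(t) > 0, True)
        t, s = t[keep], s[keep]
        if r is not None:
            r = r[keep]
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        if r is not None and np.any(r < 0):
            raise ValueError("at_risk counts must be nonnegative")
        self.times, self.survival, self.at_risk = t, s, r

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "KMCurve":
        """Read the ``time_months,survival,at_risk`` CSV dialect."""
        df = pd.read_csv(path)
        required = {"time_months", "survival"}
        if not required.issubset(df.columns):
            raise ValueError(f"KM CSV must have columns {sorted(required)}, got {list(df.columns)}")
        at_risk = None
        if "at_risk" in df.columns and df["at_risk"].notna().all():
            at_risk = df["at_risk"].to_numpy(dtype=float)
        return cls(
            times=df["time_months"].to_numpy(dtype=float),
            survival=df["survival"].to_numpy(dtype=float),
            at_risk=at_risk,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_months": self.times, "survival": self.survival})
        df["at_risk"] = self.at_risk if self.at_risk is not None else ""
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class WeibullFit:
    """Result of a least-squares Weibull fit to KM coordinates."""

    params: WeibullParams
    r_squared: float
    n_points: int
    curve_id: str | None = None

    @property
    def scale(self) -> float:
        return self.params.scale

    @property
    def shape(self) -> float:
        return self.params.shape

    def to_dict(self) -> dict:
        return {
            "curve_id": self.curve_id,
            "scale": self.params.scale,
            "shape": self.params.shape,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_weibull_to_km(curve: KMCurve, curve_id: str | None = None) -> WeibullFit:
    """Fit Weibull parameters to Kaplan-Meier coordinates by log-log least squares.

    Regresses ``log(-log S)`` on ``log t`` over points strictly inside
    0 < S < 1 with t > 0 (the linearisation is exact for Weibull data, so
    noise-free curves are recovered to solver precision).  When at-risk
    counts are present they serve as least-squares weights.  Requires at
    least three usable points.
    """
    usable = (curve.survival > 0.0) & (curve.survival < 1.0) & (curve.times > 0.0)
    if int(usable.sum()) < 3:
        raise FitError(
            f"need >= 3 points with 0 < survival < 1 and t > 0, got {int(usable.sum())}"
        )
    t = curve.times[usable]
    s = curve.survival[usable]
    w = np.ones_like(t) if curve.at_risk is None else np.maximum(curve.at_risk[usable], 0.0)
    if np.all(w == 0):
        w = np.ones_like(t)

    x = np.log(t)
    y = np.log(-np.log(s))
    # weighted linear least squares: y = intercept + slope * x
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise FitError("degenerate time values: all usable points share one time")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    if slope <= 0:
        raise FitError(f"fitted shape must be positive, got {slope}")

    resid = y - (intercept + slope * x)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return WeibullFit(
        params=WeibullParams(scale=math.exp(intercept), shape=slope),
        r_squared=float(r2),
        n_points=int(t.size),
        curve_id=curve_id,
    )
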