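"""Parametric survival for the two-state cohort model.

A Weibull law ``S(t) = exp(-scale * t**shape)`` describes overall survival in
each trial arm; ``shape`` (γ) < 1 implies a decreasing hazard.  Time ``t`` is
measured in *model units* of ``time_unit_days`` days, so the printed
shape/scale pair can be interpreted under any time-unit convention.  The
per-cycle probability of dying during the cycle that ends at ``t`` follows
the standard transformation

    P(t) = 1 - exp(scale * ((t - u)**shape - t**shape)) = 1 - S(t) / S(t - u)

with ``u`` the cycle length in model units.  Weibull parameters can be fitted
to digitized Kaplan-Meier coordinates by ordinary least squares on the
complementary log-log linearization ``ln(-ln S) = ln(scale) + shape * ln t``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("shpn_cea.survival")

__all__ = [
    "WeibullSurvival",
    "KMPoints",
    "FitError",
    "survival_at",
    "transition_probability",
    "fit_weibull",
    "median_survival",
    "calibrate_scale_to_median",
    "transition_table",
]


@dataclass(frozen=True)
class WeibullSurvival:
    """Weibull survival parameters for one arm.

    ``shape`` and ``scale`` are the γ and λ of ``S(t) = exp(-λ t^γ)`` with
    ``t`` in model units of ``time_unit_days`` days (default one 6-week
    cycle).
    """

    shape: float
    scale: float
    time_unit_days: float = 42.0

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not self.time_unit_days > 0:
            raise ValueError(f"time_unit_days must be > 0, got {self.time_unit_days}")


@dataclass(frozen=True)
class KMPoints:
    """Digitized Kaplan-Meier curve coordinates for one arm.

    ``points`` are (time in days, survival fraction) pairs with strictly
    increasing times and non-increasing survival.
    """

    points: tuple[tuple[float, float], ...]
    arm: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        times = [t for t, _ in pts]
        survs = [s for _, s in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("KM point times must be strictly increasing")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValueError("KM survival must be non-increasing")
        if survs and survs[0] > 1.0:
            raise ValueError("survival fractions cannot exceed 1")
        # S = 0 is legitimate (product-limit curve after the last event);
        # such points simply carry no information for a Weibull fit.
        if any(s < 0 for s in survs):
            raise ValueError("survival fractions must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, arm: str = "") -> "KMPoints":
        """Build from a 2-column table (time_days, survival)."""
        return cls(tuple(zip(frame.iloc[:, 0], frame.iloc[:, 1])), arm=arm)


class FitError(ValueError):
    """Raised when too few usable points remain for a Weibull fit."""


def survival_at(w: WeibullSurvival, t: float | np.ndarray) -> float | np.ndarray:
    """Survival fraction ``S(t) = exp(-scale * t**shape)`` at model time ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    out = np.exp(-w.scale * t**w.shape)
    return float(out) if out.ndim == 0 else out


def transition_probability(w: WeibullSurvival, t: float, u: float) -> float:
    """Death probability for the cycle ending at model time ``t``.

    Equals ``1 - S(t)/S(t-u)`` evaluated in closed form, so it stays in
    [0, 1) for every valid Weibull parameter pair.
    """
    if not u > 0:
        raise ValueError("cycle length u must be positive")
    if t < u:
        raise ValueError(f"cycle end time t={t} must be >= cycle length u={u}")
    p = -math.expm1(w.scale * ((t - u) ** w.shape - t**w.shape))
    # mathematically p < 1 always; when S(t)/S(t-u) underflows, float
    # rounding can hit 1.0 exactly — keep the documented open interval
    return min(p, math.nextafter(1.0, 0.0))


def median_survival(w: WeibullSurvival) -> float:
    """Median survival time in days: ``time_unit_days * (ln 2 / scale)**(1/shape)``."""
    return w.time_unit_days * (math.log(2.0) / w.scale) ** (1.0 / w.shape)


def calibrate_scale_to_median(w: WeibullSurvival, median_days: float) -> WeibullSurvival:
    """Rescale λ, holding γ fixed, so the implied median equals ``median_days``.

    Useful when a published shape/scale pair is internally inconsistent with
    the published median (the time unit of the pair being unstated).
    """
    if not median_days > 0:
        raise ValueError("median_days must be positive")
    m_units = median_days / w.time_unit_days
    return replace(w, scale=math.log(2.0) / m_units**w.shape)


def fit_weibull(
    points: KMPoints | Sequence[tuple[float, float]],
    time_unit_days: float = 42.0,
) -> WeibullSurvival:
    """Fit Weibull (shape, scale) to digitized survival-curve coordinates.

    Ordinary least squares of ``ln(-ln S)`` on ``ln t`` (slope = shape,
    intercept = ln scale).  Points with S outside the open interval (0, 1)
    — e.g. the t=0, S=1 anchor — carry no information under the
    complementary log-log transform and are dropped (and logged); at least
    3 usable points must remain.  The linearization is exact on noiseless
    Weibull data.
    """
    if isinstance(points, KMPoints):
        raw = points.points
    else:
        raw = tuple((float(t), float(s)) for t, s in points)
    usable = [(t, s) for t, s in raw if 0.0 < s < 1.0 and t > 0]
    dropped = [p for p in raw if p not in usable]
    if dropped:
        log.debug("fit_weibull dropped %d uninformative point(s): %s", len(dropped), dropped)
    if len(usable) < 3:
        raise FitError(
            f"need >=3 points with survival strictly in (0,1); "
            f"got {len(usable)} usable, dropped {dropped}"
        )
    t_units = np.array([t for t, _ in usable]) / time_unit_days
    s = np.array([s for _, s in usable])
    x = np.log(t_units)
    y = np.log(-np.log(s))
    shape, intercept = np.polyfit(x, y, 1)
    return WeibullSurvival(shape=float(shape), scale=float(math.exp(intercept)),
                           time_unit_days=time_unit_days)


def transition_table(w: WeibullSurvival, n_cycles: int, u: float = 1.0) -> pd.DataFrame:
    """Per-cycle death probabilities (cycle, p_death) for cycles 1..n_cycles."""
    rows = [(k, transition_probability(w, k * u, u)) for k in range(1, n_cycles + 1)]
    return pd.DataFrame(rows, columns=["cycle", "p_death"])
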