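"""Protein half-life estimation from decay (cycloheximide-chase) series.

Under translation arrest a protein's abundance decays exponentially,
``S(t) = S0 * exp(-k t)``, so ordinary least squares of ``ln S`` on time
yields the decay rate ``k = -slope`` and the half-life ``t_half = ln2/k``.
Replicate series are pooled: the regression runs on all (time, ln signal)
pairs.  Nonpositive signals (densitometry floor noise) are dropped before
the log transform, with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["DecaySeries", "HalfLifeEstimate", "HalfLifeEstimator",
           "estimate_half_life", "estimate_from_frame"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecaySeries:
    """One decay time course: signal vs. time for a single species.

    ``signal`` may be raw or normalized; the estimate is scale-invariant.
    """

    species: str
    time_h: np.ndarray
    signal: np.ndarray
    replicate: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size and t[0] != 0.0:
            raise ValueError("decay series must start at time 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing within a replicate")
        if np.any(s < 0):
            raise ValueError("signals must be nonnegative")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Result of a log-linear decay fit.

    ``t_half_h = ln2 / k_per_h`` exactly; a non-decaying series (slope of
    ln-signal >= 0) is flagged ``no_decay`` with an infinite half-life
    sentinel rather than a silent number.
    """

    t_half_h: float
    k_per_h: float
    r_squared: float
    n_points: int
    no_decay: bool = False

    def to_dict(self) -> dict:
        return {
            "t_half_h": self.t_half_h,
            "k_per_h": self.k_per_h,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "no_decay": self.no_decay,
        }


class HalfLifeEstimator(BaseEstimator):
    """Sklearn-style estimator for exponential-decay half-lives.

    Fits ``ln y = intercept + slope * t`` by OLS on the pooled points.

    Parameters
    ----------
    min_points : int, default 3
        Minimum number of positive-signal points required after censoring.

    Attributes
    ----------
    t_half_ : float
        Estimated half-life in hours (``inf`` when no decay is detected).
    decay_rate_ : float
        ``k = -slope`` in per hour.
    r_squared_ : float
        Coefficient of determination of the log-linear fit.
    n_points_ : int
        Number of points used after censoring.
    no_decay_ : bool
        True when the fitted slope is >= 0.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, t, y) -> "HalfLifeEstimator":
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        keep = y > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} nonpositive signal value(s) before log transform",
                UserWarning, stacklevel=2,
            )
        t, y = t[keep], y[keep]
        if t.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} positive-signal points, got {t.size}"
            )
        logy = np.log(y)
        slope, intercept = np.polyfit(t, logy, 1)
        resid = logy - (intercept + slope * t)
        ss_res = float(resid @ resid)
        ss_tot = float(((logy - logy.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.decay_rate_ = float(-slope)
        self.n_points_ = int(t.size)
        self.no_decay_ = self.decay_rate_ <= 0
        self.t_half_ = math.inf if self.no_decay_ else LN2 / self.decay_rate_
        return self

    def result_(self) -> HalfLifeEstimate:
        return HalfLifeEstimate(
            t_half_h=self.t_half_,
            k_per_h=self.decay_rate_,
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            no_decay=self.no_decay_,
        )


def estimate_half_life(series, signal=None, *, min_points: int = 3) -> HalfLifeEstimate:
    """Estimate a half-life from a :class:`DecaySeries`, a list of replicate
    series (pooled), or raw ``(time, signal)`` arrays.
    """
    if signal is not None:
        t, y = np.asarray(series, dtype=float), np.asarray(signal, dtype=float)
    elif isinstance(series, DecaySeries):
        t, y = series.time_h, series.signal
    else:  # iterable of DecaySeries -> pool replicates
        parts = list(series)
        t = np.concatenate([s.time_h for s in parts])
        y = np.concatenate([s.signal for s in parts])
    est = HalfLifeEstimator(min_points=min_points).fit(t, y)
    return est.result_()


def estimate_from_frame(df: pd.DataFrame, species: str | None = None,
                        *, min_points: int = 3) -> dict[str, HalfLifeEstimate]:
    """Fit half-lives from a chase table with columns
    ``species, replicate, time_h, signal`` (replicates pooled per species).
    """
    required = {"species", "time_h", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chase table missing columns: {sorted(missing)}")
    out: dict[str, HalfLifeEstimate] = {}
    for name, grp in df.groupby("species", sort=True):
        if species is not None and name != species:
            continue
        out[name] = estimate_half_life(
            grp["time_h"].to_numpy(), grp["signal"].to_numpy(), min_points=min_points
        )
    if species is not None and species not in out:
        raise ValueError(f"species {species!r} not present in chase table")
    return out
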