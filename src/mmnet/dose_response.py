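"""Four-parameter logistic (4PL) dose-response fitting and IC50 extraction.

Cell survival against the logarithm of inhibitor concentration follows the
standard sigmoid

    y(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

fit by least squares on log10-dose with a deterministic initialization
(top = max response, bottom = min response, ic50 = geometric mid-dose,
slope = 1).  A flat response is flagged degenerate instead of fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["DoseResponseCurve", "IC50Fit", "FourParamLogisticIC50",
           "four_param_logistic", "fit_ic50"]


def four_param_logistic(dose, ic50, hill, top, bottom):
    """4PL survival at the given dose(s); decreasing in dose for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _4pl_logdose(logd, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logd - log_ic50) * hill))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Viability measurements for one drug x cell line.

    ``responses`` is (replicate x dose) percent survival; at least four
    distinct positive doses are required for fitting (log-dose axis).
    """

    drug: str
    cell_line: str
    doses_uM: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_uM, dtype=float)
        r = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive (log-dose axis)")
        if np.unique(d).size < 4:
            raise ValueError("need at least 4 distinct doses for a 4PL fit")
        if r.shape[1] != d.size:
            raise ValueError("responses must be (n_replicates, n_doses)")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "doses_uM", d)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class IC50Fit:
    """Fitted 4PL parameters; ``extrapolated`` flags an IC50 outside the
    dose span, ``degenerate`` a flat-response curve that was not fitted."""

    ic50_uM: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    extrapolated: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"ic50_uM": self.ic50_uM, "hill_slope": self.hill_slope,
                "top": self.top, "bottom": self.bottom, "rss": self.rss,
                "extrapolated": self.extrapolated, "degenerate": self.degenerate}


class FourParamLogisticIC50(BaseEstimator, RegressorMixin):
    """Sklearn-style 4PL dose-response estimator.

    Parameters
    ----------
    flat_tol : float, default 1e-9
        Response range below which the curve is flagged degenerate.
    maxfev : int, default 10000
        Iteration budget for the least-squares solver.

    Attributes
    ----------
    ic50_ : float
    hill_slope_ : float
    top_, bottom_ : float
    rss_ : float
    extrapolated_ : bool
        True when the fitted IC50 lies outside the dose span.
    degenerate_ : bool
        True for a flat response; fitted parameters are then the trivial
        constant fit (top = bottom = mean response, ic50 = nan).
    """

    def __init__(self, flat_tol: float = 1e-9, maxfev: int = 10000):
        self.flat_tol = flat_tol
        self.maxfev = maxfev

    def fit(self, doses, responses) -> "FourParamLogisticIC50":
        d = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(responses, dtype=float).ravel()
        if d.shape != y.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if np.ptp(y) <= self.flat_tol:
            self.degenerate_ = True
            self.ic50_ = math.nan
            self.hill_slope_ = math.nan
            self.top_ = self.bottom_ = float(y.mean())
            self.rss_ = float(((y - y.mean()) ** 2).sum())
            self.extrapolated_ = False
            return self

        logd = np.log10(d)
        # documented deterministic initialization
        p0 = [float(np.mean([logd.min(), logd.max()])), 1.0, float(y.max()), float(y.min())]
        try:
            popt, _ = curve_fit(_4pl_logdose, logd, y, p0=p0, maxfev=self.maxfev)
        except RuntimeError as exc:
            raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
        log_ic50, hill, top, bottom = popt
        if top < bottom:  # equivalent curve with positive orientation
            top, bottom, hill = bottom, top, -hill
        self.degenerate_ = False
        self.ic50_ = float(10.0 ** log_ic50)
        self.hill_slope_ = float(hill)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        resid = y - _4pl_logdose(logd, log_ic50, *popt[1:])
        self.rss_ = float(resid @ resid)
        self.extrapolated_ = not (d.min() <= self.ic50_ <= d.max())
        return self

    def predict(self, doses) -> np.ndarray:
        return four_param_logistic(doses, self.ic50_, self.hill_slope_,
                                   self.top_, self.bottom_)

    def result_(self) -> IC50Fit:
        return IC50Fit(ic50_uM=self.ic50_, hill_slope=self.hill_slope_,
                       top=self.top_, bottom=self.bottom_, rss=self.rss_,
                       extrapolated=self.extrapolated_,
                       degenerate=self.degenerate_)


def fit_ic50(curve: DoseResponseCurve, *, pooled: bool = True) -> IC50Fit:
    """Fit a 4PL to a dose-response curve (replicates pooled by default)."""
    if pooled:
        d = np.tile(curve.doses_uM, curve.responses.shape[0])
        y = curve.responses.ravel()
    else:
        d, y = curve.doses_uM, curve.responses.mean(axis=0)
    return FourParamLogisticIC50().fit(d, y).result_()


def fit_ic50_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every drug x cell_line group of a viability table with columns
    ``drug, cell_line, replicate, dose_uM, survival_pct``."""
    required = {"drug", "cell_line", "dose_uM", "survival_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    rows = []
    for (drug, cell), grp in df.groupby(["drug", "cell_line"], sort=True):
        fit = FourParamLogisticIC50().fit(
            grp["dose_uM"].to_numpy(), grp["survival_pct"].to_numpy()
        ).result_()
        rows.append({"drug": drug, "cell_line": cell, **fit.to_dict()})
    return pd.DataFrame(rows)
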