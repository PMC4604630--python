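"""Target analyses applied to completed (or complete-case) datasets.

Each estimand maps a fully observed (y, x) pair of vectors to a point
estimate and a standard error:

- ``marginal_mean``: sample mean of y; se = sd(y, ddof=1) / sqrt(n)
- ``marginal_proportion``: sample proportion of y == 1; binomial plug-in se
- ``linear_slope``: OLS slope of y on x with the conventional se
- ``logistic_slope``: logistic-regression MLE slope with Wald se
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datagen import IncompleteSample
from .exceptions import AnalysisError

__all__ = ["ESTIMANDS", "PerImputationEstimate", "analyze", "complete_case",
           "default_estimands"]

ESTIMANDS = ("marginal_mean", "marginal_proportion", "linear_slope", "logistic_slope")

#: estimands compatible with each outcome type
_BY_OUTCOME = {
    "continuous": ("marginal_mean", "linear_slope"),
    "binary": ("marginal_proportion", "logistic_slope"),
}


def default_estimands(outcome_type: str) -> tuple[str, ...]:
    try:
        return _BY_OUTCOME[outcome_type]
    except KeyError:
        raise AnalysisError(f"unknown outcome type {outcome_type!r}") from None


@dataclass(frozen=True)
class PerImputationEstimate:
    """Point estimate and standard error from one completed dataset."""

    estimate: float
    se: float

    def __post_init__(self):
        if not (np.isfinite(self.estimate) and np.isfinite(self.se) and self.se > 0):
            raise AnalysisError(
                f"estimate/se must be finite with se > 0 "
                f"(got {self.estimate!r}, {self.se!r})")


def analyze(y, x, estimand: str) -> PerImputationEstimate:
    """Compute one estimand on a fully observed dataset."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if estimand not in ESTIMANDS:
        raise AnalysisError(f"unknown estimand {estimand!r}")
    if y.shape != x.shape or y.ndim != 1:
        raise AnalysisError("y and x must be 1-d arrays of equal length")
    if y.size < 3:
        raise AnalysisError("need at least 3 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise AnalysisError("analyze requires fully observed data")

    n = y.size
    if estimand == "marginal_mean":
        sd = y.std(ddof=1)
        if sd == 0:
            raise AnalysisError("outcome is constant; se would be zero")
        return PerImputationEstimate(float(y.mean()), float(sd / np.sqrt(n)))

    if estimand == "marginal_proportion":
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise AnalysisError("marginal_proportion requires a 0/1 outcome")
        p = float(y.mean())
        if p in (0.0, 1.0):
            raise AnalysisError("degenerate proportion; se would be zero")
        return PerImputationEstimate(p, float(np.sqrt(p * (1 - p) / n)))

    design = sm.add_constant(x, has_constant="add")
    if estimand == "linear_slope":
        if np.ptp(x) == 0:
            raise AnalysisError("covariate is constant; slope undefined")
        fit = sm.OLS(y, design).fit()
        return PerImputationEstimate(float(fit.params[1]), float(fit.bse[1]))

    # logistic_slope
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise AnalysisError("logistic_slope requires a 0/1 outcome")
    if y.min() == y.max():
        raise AnalysisError("logistic_slope requires both outcome classes")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, design).fit(disp=0)
    except Exception as err:
        raise AnalysisError(f"logistic fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise AnalysisError("logistic fit did not converge")
    return PerImputationEstimate(float(fit.params[1]), float(fit.bse[1]))


def complete_case(sample: IncompleteSample, estimand: str) -> PerImputationEstimate:
    """Run the target analysis on the rows with the outcome observed."""
    obs = sample.observed_index
    if obs.size < 3:
        raise AnalysisError("complete-case analysis needs at least 3 observed outcomes")
    return analyze(sample.y[obs], sample.x[obs], estimand)
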