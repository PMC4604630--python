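"""Rubin's-rules pooling and delta-weighted MNAR pooling.

The MAR combination of m per-imputation estimates theta_j with standard
errors se_j is

    theta_MAR = mean(theta_j)
    V = V_W + (1 + 1/m) V_B,   V_W = mean(se_j^2),
                               V_B = sum((theta_j - theta_MAR)^2) / (m - 1).

The MNAR sensitivity analysis reweights the same per-imputation estimates
by importance weights derived from the selection-model sensitivity
parameter delta. Each imputed dataset j receives the raw weight

    w~_j(delta) = exp(-delta * S_j),

where S_j is the sum of the imputed values in dataset j, normalised to
w_j = w~_j / sum_k w~_k. The MNAR estimate is the weighted mean
sum_j w_j theta_j, with weighted variance components
V_W = sum_j w_j se_j^2 and V_B = sum_j w_j (theta_j - theta_MNAR)^2
combined with the same (1 + 1/m) inflation. The weighted between-variance
is used verbatim (no m/(m-1) correction), so at delta = 0 it equals
(m-1)/m times the Rubin between-variance while the point estimates
coincide exactly.

Weights are computed in log space with max-subtraction, so the raw
weights are reported up to a common positive factor (they are only ever
used after normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimands import PerImputationEstimate
from .exceptions import PoolingError, WeightError

__all__ = ["PooledEstimate", "DeltaWeightSet", "rubin_pool", "delta_weights",
           "mnar_pool"]


@dataclass(frozen=True)
class PooledEstimate:
    """A pooled point estimate with within/between variance components."""

    estimate: float
    within: float
    between: float
    m: int
    mechanism: str  # "MAR" or "MNAR"
    delta: float | None = None
    estimand: str | None = None

    def __post_init__(self):
        if self.mechanism not in ("MAR", "MNAR"):
            raise PoolingError("mechanism must be 'MAR' or 'MNAR'")
        if self.mechanism == "MNAR" and self.delta is None:
            raise PoolingError("MNAR pooled estimate requires delta")
        if self.within < 0 or self.between < 0:
            raise PoolingError("variance components must be nonnegative")

    @property
    def variance(self) -> float:
        """Total variance: within + (1 + 1/m) * between."""
        return self.within + (1.0 + 1.0 / self.m) * self.between

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-reference confidence interval."""
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.estimate - z * self.se, self.estimate + z * self.se)

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand,
            "mechanism": self.mechanism,
            "m": self.m,
            "delta": self.delta,
            "estimate": self.estimate,
            "se": self.se,
            "variance": self.variance,
            "within": self.within,
            "between": self.between,
        }


@dataclass(frozen=True)
class DeltaWeightSet:
    """Raw and normalised importance weights for one delta.

    ``raw`` is exp(-delta*(S_j - min-shift)) — i.e. the Eq-style weights up
    to a common positive factor; ``normalized`` sums to one.
    """

    delta: float
    raw: np.ndarray
    normalized: np.ndarray
    sums: np.ndarray

    def __post_init__(self):
        for name in ("raw", "normalized", "sums"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isfinite(self.normalized)):
            raise WeightError("non-finite normalised weights")
        if abs(self.normalized.sum() - 1.0) > 1e-12:
            raise WeightError("normalised weights must sum to 1")

    @property
    def m(self) -> int:
        return self.raw.size

    @property
    def max_weight(self) -> float:
        return float(self.normalized.max())

    @property
    def effective_sample_size(self) -> float:
        """1 / sum(w_j^2): m when uniform, 1 when degenerate."""
        return float(1.0 / np.sum(self.normalized ** 2))


def rubin_pool(estimates: Sequence[PerImputationEstimate],
               estimand: str | None = None) -> PooledEstimate:
    """Pool per-imputation estimates under MAR with Rubin's rules."""
    m = len(estimates)
    if m < 2:
        raise PoolingError("Rubin pooling needs m >= 2 (between-variance undefined)")
    theta = np.array([e.estimate for e in estimates])
    se = np.array([e.se for e in estimates])
    point = float(theta.mean())
    within = float(np.mean(se ** 2))
    between = float(np.sum((theta - point) ** 2) / (m - 1))
    return PooledEstimate(point, within, between, m, "MAR", estimand=estimand)


def delta_weights(imputations, delta: float) -> DeltaWeightSet:
    """Importance weights exp(-delta * S_j), normalised, computed stably.

    ``imputations`` may be an :class:`~misens.impute.ImputationSet` or a
    plain array of per-imputation imputed-value sums S_j.
    """
    sums = np.asarray(getattr(imputations, "sums", imputations), dtype=float)
    if sums.ndim != 1 or sums.size < 1:
        raise WeightError("need at least one imputed-value sum")
    if not (np.all(np.isfinite(sums)) and np.isfinite(delta)):
        raise WeightError("sums and delta must be finite")
    logw = -float(delta) * sums
    raw = np.exp(logw - logw.max())
    normalized = raw / raw.sum()
    # exact renormalisation so the sum-to-one invariant holds to 1e-12
    normalized = normalized / normalized.sum()
    return DeltaWeightSet(float(delta), raw, normalized, sums)


def mnar_pool(estimates: Sequence[PerImputationEstimate],
              weights: DeltaWeightSet,
              estimand: str | None = None) -> PooledEstimate:
    """Pool per-imputation estimates under MNAR with importance weights."""
    m = len(estimates)
    if m != weights.m:
        raise PoolingError("estimates and weights must have matching length")
    if m < 2:
        raise PoolingError("weighted pooling needs m >= 2")
    theta = np.array([e.estimate for e in estimates])
    se = np.array([e.se for e in estimates])
    w = weights.normalized
    point = float(w @ theta)
    within = float(w @ se ** 2)
    between = float(w @ (theta - point) ** 2)
    return PooledEstimate(point, within, between, m, "MNAR",
                          delta=weights.delta, estimand=estimand)
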