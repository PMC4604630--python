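"""Weight diagnostics and graphical selection of the sensitivity parameter.

Two diagnostics probe the first importance-sampling condition (the MNAR
estimate must lie inside the range of the per-imputation MAR estimates):

- a scatter of the normalised weights against the per-imputation
  estimates, with the uniform reference level 1/m and the pooled MAR
  estimate marked, which exposes imputations that dominate the weighted
  average;
- the running weighted MNAR estimate over the first k imputations, which
  exposes vertical steps where a single late imputation grabs the weight.

The delta-range selection follows the two graphical rules for a plausible
sensitivity-parameter range: over a grid of candidate delta values, keep
those where (i) the maximum normalised weight is at most a cap (default
0.5) and (ii) at least ``min_count`` (default 5) normalised weights lie at
or above 1/m. "At or above" is read with tolerance 1e-12; otherwise
delta = 0, where every weight equals 1/m exactly, would itself fail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DiagnosticError
from .estimands import PerImputationEstimate
from .pooling import DeltaWeightSet, delta_weights, rubin_pool

__all__ = ["WeightDiagnostic", "RunningEstimate", "DeltaRange",
           "weight_diagnostic", "running_mnar", "select_delta_range",
           "default_delta_grid"]


def _estimate_array(estimates) -> np.ndarray:
    return np.array([e.estimate if isinstance(e, PerImputationEstimate) else float(e)
                     for e in estimates])


@dataclass(frozen=True)
class WeightDiagnostic:
    """Normalised weight vs per-imputation estimate pairs, plus references."""

    weights: np.ndarray
    estimates: np.ndarray
    mar_estimate: float
    delta: float

    @property
    def m(self) -> int:
        return self.weights.size

    @property
    def reference(self) -> float:
        """Uniform-weight level 1/m (the MAR configuration)."""
        return 1.0 / self.m

    @property
    def max_weight(self) -> float:
        return float(self.weights.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"imputation": np.arange(self.m),
                             "weight": self.weights,
                             "estimate": self.estimates})

    def plot(self, ax=None):
        """Scatter of w_j against theta_j with 1/m and MAR reference lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.estimates, self.weights, s=14, color="black")
        ax.axhline(self.reference, linestyle=":", color="grey",
                   label=f"uniform 1/m = {self.reference:.3g}")
        ax.axvline(self.mar_estimate, linestyle="--", color="grey",
                   label="pooled MAR estimate")
        ax.set_xlabel("per-imputation estimate under MAR")
        ax.set_ylabel("normalised weight")
        ax.set_title(f"weight diagnostic (delta = {self.delta:g})")
        ax.legend(loc="best", fontsize="small")
        return ax


@dataclass(frozen=True)
class RunningEstimate:
    """Partial MNAR estimates over the first k = 1..m imputations."""

    values: np.ndarray
    estimates: np.ndarray
    mar_estimate: float
    delta: float

    @property
    def m(self) -> int:
        return self.values.size

    @property
    def final(self) -> float:
        return float(self.values[-1])

    def plot(self, ax=None):
        """Running MNAR estimate vs k, with per-imputation estimates as a rug."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, self.m + 1)
        ax.plot(k, self.values, color="black", lw=1.2,
                label="running MNAR estimate")
        ax.axhline(self.mar_estimate, linestyle="--", color="grey",
                   label="pooled MAR estimate")
        ax.set_xlabel("number of imputations")
        ax.set_ylabel("estimate")
        ax.set_title(f"running MNAR estimate (delta = {self.delta:g})")
        right = ax.twinx()
        right.plot(np.full(self.m, self.m), self.estimates, marker="_",
                   linestyle="none", color="tab:blue", alpha=0.5, markersize=8)
        right.set_ylabel("per-imputation MAR estimates", color="tab:blue")
        right.set_ylim(ax.get_ylim())
        ax.legend(loc="best", fontsize="small")
        return ax


@dataclass(frozen=True)
class DeltaRange:
    """Grid search result for the plausible sensitivity-parameter range."""

    grid: np.ndarray
    max_weight: np.ndarray
    count_above: np.ndarray
    passing: np.ndarray
    lo: float | None
    hi: float | None
    max_weight_cap: float
    min_count: int
    m: int

    @property
    def is_empty(self) -> bool:
        return self.lo is None

    @property
    def interval(self) -> tuple[float, float] | None:
        return None if self.is_empty else (self.lo, self.hi)

    def contains(self, delta: float) -> bool:
        return (not self.is_empty) and self.lo <= delta <= self.hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta": self.grid, "max_weight": self.max_weight,
                             "count_above": self.count_above,
                             "passing": self.passing})

    def plot(self, sums=None, ax=None, max_curves: int = 300):
        """Normalised-weight curves w_j(delta) with the selected range marked.

        ``sums`` (the per-imputation imputed-value sums) is required to draw
        the curves; without it only max-weight and the range are shown.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if sums is not None:
            sums = np.asarray(sums, dtype=float)
            logw = -np.outer(sums, self.grid)          # (m, G)
            logw -= logw.max(axis=0, keepdims=True)
            w = np.exp(logw)
            w /= w.sum(axis=0, keepdims=True)
            for row in w[:max_curves]:
                ax.plot(self.grid, row, color="black", lw=0.4, alpha=0.35)
        else:
            ax.plot(self.grid, self.max_weight, color="black",
                    label="max normalised weight")
            ax.legend(loc="best", fontsize="small")
        ax.axhline(self.max_weight_cap, linestyle=":", color="tab:red")
        ax.axhline(1.0 / self.m, linestyle=":", color="grey")
        if not self.is_empty:
            ax.axvline(self.lo, linestyle="--", color="tab:blue")
            ax.axvline(self.hi, linestyle="--", color="tab:blue")
        ax.set_xlabel("delta")
        ax.set_ylabel("normalised weight")
        return ax


def weight_diagnostic(imputations, estimates: Sequence[PerImputationEstimate],
                      delta: float) -> WeightDiagnostic:
    """Pair each imputation's normalised weight with its MAR estimate."""
    weights = delta_weights(imputations, delta)
    theta = _estimate_array(estimates)
    if theta.size != weights.m:
        raise DiagnosticError("estimates and imputations must have matching length")
    mar = rubin_pool(list(estimates)).estimate if theta.size >= 2 else float(theta[0])
    return WeightDiagnostic(weights.normalized, theta, mar, float(delta))


def running_mnar(estimates: Sequence[PerImputationEstimate],
                 weights: DeltaWeightSet) -> RunningEstimate:
    """Weighted MNAR estimate recomputed cumulatively over imputations.

    The k-th value uses the raw weights of the first k imputations,
    renormalised over those k, in natural imputation order.
    """
    theta = _estimate_array(estimates)
    if theta.size != weights.m:
        raise DiagnosticError("estimates and weights must have matching length")
    num = np.cumsum(weights.raw * theta)
    den = np.cumsum(weights.raw)
    mar = float(theta.mean())
    return RunningEstimate(num / den, theta, mar, weights.delta)


def default_delta_grid(lo: float = -2.0, hi: float = 2.0,
                       step: float = 0.01) -> np.ndarray:
    """Default candidate grid: lo..hi inclusive, rounded to the step."""
    k = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(k + 1), 10)


def select_delta_range(imputations, grid=None, max_weight_cap: float = 0.5,
                       min_count: int = 5, tol: float = 1e-12) -> DeltaRange:
    """Graphical-rule selection of a plausible range for delta.

    A grid value passes when the maximum normalised weight is at most
    ``max_weight_cap`` and at least ``min_count`` weights are >= 1/m - tol.
    The reported interval is the widest contiguous passing run that
    contains delta = 0 when 0 is on the grid and passes; otherwise the
    widest passing run. An empty passing set yields an empty range, not an
    error.
    """
    sums = np.asarray(getattr(imputations, "sums", imputations), dtype=float)
    m = sums.size
    if m < min_count:
        raise DiagnosticError(f"need at least min_count={min_count} imputations")
    grid = default_delta_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise DiagnosticError("grid must be nonempty and strictly increasing")

    logw = -np.outer(sums, grid)                      # (m, G)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=0, keepdims=True)
    max_weight = w.max(axis=0)
    count_above = (w >= 1.0 / m - tol).sum(axis=0)
    passing = (max_weight <= max_weight_cap) & (count_above >= min_count)

    lo = hi = None
    if passing.any():
        # contiguous runs of passing grid points
        idx = np.flatnonzero(passing)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks], idx[-1]]
        zero_pos = np.flatnonzero(np.isclose(grid, 0.0))
        chosen = None
        if zero_pos.size and passing[zero_pos[0]]:
            z = zero_pos[0]
            for s, e in zip(starts, ends):
                if s <= z <= e:
                    chosen = (s, e)
                    break
        if chosen is None:
            widths = grid[ends] - grid[starts]
            k = int(np.argmax(widths))
            chosen = (starts[k], ends[k])
        lo, hi = float(grid[chosen[0]]), float(grid[chosen[1]])

    return DeltaRange(grid, max_weight, count_above, passing, lo, hi,
                      max_weight_cap, min_count, m)


def plot_sum_histogram(imputations, ax=None, bins: int = 30):
    """Histogram of the per-imputation imputed-value sums S_j."""
    import matplotlib.pyplot as plt

    sums = np.asarray(getattr(imputations, "sums", imputations), dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(sums, bins=bins, color="lightgrey", edgecolor="black")
    ax.set_xlabel("sum of imputed values $S_j$")
    ax.set_ylabel("imputations")
    return ax
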