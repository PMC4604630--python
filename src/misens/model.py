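"""Model/Results surface for the delta-weighting sensitivity analysis.

:class:`MNARSensitivity` is built from a dataset with a partially observed
outcome and a fully observed covariate; :meth:`MNARSensitivity.fit`
multiply imputes the outcome under MAR, analyses each completed dataset,
pools with Rubin's rules and reweights with the selection-model
sensitivity parameter delta, returning a :class:`MNARSensitivityResults`
that carries the MAR and MNAR estimates, their variance decompositions,
the importance weights and the weight diagnostics.

Example
-------
>>> import pandas as pd
>>> from misens import MNARSensitivity
>>> data = pd.read_csv("study.csv")          # columns x, y; y partially observed
>>> model = MNARSensitivity.from_dataframe(data, outcome="y", covariate="x")
>>> results = model.fit(m=50, delta=0.5, seed=7)
>>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import IncompleteSample, read_sample_csv
from .diagnostics import (DeltaRange, running_mnar, select_delta_range,
                          weight_diagnostic)
from .estimands import analyze, complete_case, default_estimands
from .exceptions import ParameterError
from .impute import ImputationSet, impute_logistic, impute_normal
from .pooling import (DeltaWeightSet, PooledEstimate, delta_weights, mnar_pool,
                      rubin_pool)

__all__ = ["MNARSensitivity", "MNARSensitivityResults"]


class MNARSensitivity:
    """Delta-weighting MNAR sensitivity model for one incomplete dataset.

    Parameters
    ----------
    sample : IncompleteSample
        Covariate, partially observed outcome and observation indicator.
    outcome_type : {"continuous", "binary"}, optional
        Inferred from the observed outcome values when omitted (binary if
        every observed value is 0 or 1).
    estimands : sequence of str, optional
        Target analyses; defaults to the marginal parameter and the slope
        appropriate for the outcome type.
    """

    def __init__(self, sample: IncompleteSample, outcome_type: str | None = None,
                 estimands=None):
        self.sample = sample
        observed = sample.y[sample.observed_index]
        if outcome_type is None:
            outcome_type = ("binary" if np.all(np.isin(observed, [0.0, 1.0]))
                            else "continuous")
        if outcome_type not in ("continuous", "binary"):
            raise ParameterError("outcome_type must be 'continuous' or 'binary'")
        self.outcome_type = outcome_type
        self.estimands = tuple(estimands) if estimands else default_estimands(outcome_type)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str = "y",
                       covariate: str = "x", outcome_type: str | None = None,
                       estimands=None) -> "MNARSensitivity":
        y = data[outcome].to_numpy(dtype=float)
        x = data[covariate].to_numpy(dtype=float)
        r = (~np.isnan(y)).astype(int)
        return cls(IncompleteSample(x=x, y=y, r=r), outcome_type, estimands)

    @classmethod
    def from_csv(cls, path, outcome_type: str | None = None,
                 estimands=None) -> "MNARSensitivity":
        return cls(read_sample_csv(path), outcome_type, estimands)

    def impute(self, m: int, seed=None) -> ImputationSet:
        impute_fn = (impute_normal if self.outcome_type == "continuous"
                     else impute_logistic)
        return impute_fn(self.sample, m, seed)

    def fit(self, m: int = 50, delta: float = 0.0,
            seed=None) -> "MNARSensitivityResults":
        """Impute, analyse, pool under MAR, and reweight for ``delta``."""
        imputations = self.impute(m, seed)
        per_imputation = {
            estimand: [analyze(imputations.completed_y[j], self.sample.x, estimand)
                       for j in range(imputations.m)]
            for estimand in self.estimands}
        weights = delta_weights(imputations, delta)
        mar = {e: rubin_pool(ests, estimand=e)
               for e, ests in per_imputation.items()}
        mnar = {e: mnar_pool(ests, weights, estimand=e)
                for e, ests in per_imputation.items()}
        cc = {e: complete_case(self.sample, e) for e in self.estimands}
        return MNARSensitivityResults(self, imputations, per_imputation,
                                      weights, mar, mnar, cc)


@dataclass
class MNARSensitivityResults:
    """Fitted MAR and delta-weighted MNAR estimates for one dataset."""

    model: MNARSensitivity
    imputations: ImputationSet
    per_imputation: dict
    weights: DeltaWeightSet
    mar: dict[str, PooledEstimate]
    mnar: dict[str, PooledEstimate]
    complete_case: dict

    @property
    def m(self) -> int:
        return self.imputations.m

    @property
    def delta(self) -> float:
        return self.weights.delta

    @property
    def max_weight(self) -> float:
        return self.weights.max_weight

    def estimates_frame(self) -> pd.DataFrame:
        """Tidy table of complete-case, MAR and MNAR estimates."""
        rows = []
        for estimand in self.model.estimands:
            cc = self.complete_case[estimand]
            rows.append({"estimand": estimand, "method": "complete_case",
                         "estimate": cc.estimate, "se": cc.se,
                         "delta": np.nan})
            for method, pooled in (("mi_mar", self.mar[estimand]),
                                   ("mnar_weighted", self.mnar[estimand])):
                rows.append({"estimand": estimand, "method": method,
                             "estimate": pooled.estimate, "se": pooled.se,
                             "delta": (pooled.delta if method == "mnar_weighted"
                                       else np.nan)})
        return pd.DataFrame(rows)

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable summary table."""
        s = self.model.sample
        lines = [
            "Delta-weighting MNAR sensitivity analysis",
            "=" * 61,
            f"outcome type: {self.model.outcome_type:<12}  n: {s.n}"
            f"  observed: {s.n_observed}  missing: {s.n_missing}",
            f"imputations (m): {self.m}    delta: {self.delta:g}"
            f"    max weight: {self.max_weight:.3f}"
            f"    ESS: {self.weights.effective_sample_size:.1f}",
            "-" * 61,
            f"{'estimand':<20} {'method':<15} {'estimate':>9} {'se':>8}"
            f" {'95% CI':>16}",
            "-" * 61,
        ]
        for estimand in self.model.estimands:
            cc = self.complete_case[estimand]
            z = 1.959963984540054
            lines.append(
                f"{estimand:<20} {'complete case':<15} {cc.estimate:>9.3f}"
                f" {cc.se:>8.3f} [{cc.estimate - z * cc.se:>6.3f},"
                f" {cc.estimate + z * cc.se:>6.3f}]")
            for label, pooled in (("MI (MAR)", self.mar[estimand]),
                                  ("MNAR weighted", self.mnar[estimand])):
                lo, hi = pooled.conf_int(alpha)
                lines.append(
                    f"{estimand:<20} {label:<15} {pooled.estimate:>9.3f}"
                    f" {pooled.se:>8.3f} [{lo:>6.3f}, {hi:>6.3f}]")
        lines.append("-" * 61)
        lines.append("MNAR variance uses weighted within/between components; "
                     "CIs use a normal reference.")
        return "\n".join(lines)

    def weight_diagnostic(self, estimand: str | None = None):
        estimand = estimand or self.model.estimands[0]
        return weight_diagnostic(self.imputations,
                                 self.per_imputation[estimand], self.delta)

    def running_estimate(self, estimand: str | None = None):
        estimand = estimand or self.model.estimands[0]
        return running_mnar(self.per_imputation[estimand], self.weights)

    def plot_weights(self, estimand: str | None = None, ax=None):
        return self.weight_diagnostic(estimand).plot(ax=ax)

    def plot_running(self, estimand: str | None = None, ax=None):
        return self.running_estimate(estimand).plot(ax=ax)

    def select_delta_range(self, grid=None, max_weight_cap: float = 0.5,
                           min_count: int = 5) -> DeltaRange:
        """Graphical-rule plausible range for delta from this imputation set."""
        return select_delta_range(self.imputations, grid=grid,
                                  max_weight_cap=max_weight_cap,
                                  min_count=min_count)

    def to_dict(self) -> dict:
        return {
            "outcome_type": self.model.outcome_type,
            "m": self.m,
            "delta": self.delta,
            "max_weight": self.max_weight,
            "mar": {e: p.to_dict() for e, p in self.mar.items()},
            "mnar": {e: p.to_dict() for e, p in self.mnar.items()},
            "complete_case": {e: {"estimate": c.estimate, "se": c.se}
                              for e, c in self.complete_case.items()},
        }
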