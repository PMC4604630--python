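"""Proper multiple imputation of a partially observed outcome under MAR.

Both imputation models regress the outcome on an intercept and the single
fully observed covariate, fitted to the complete cases, and draw the model
parameters anew for every imputation (proper, Bayesian draws) rather than
plugging in point estimates.

Continuous outcome (normal-linear model). For imputation j:

1. draw the residual variance from its scaled inverse chi-square posterior,
   ``sigma*^2 = sigma_hat^2 * (n0 - q) / chisq(n0 - q)``, where
   ``sigma_hat^2`` is the unbiased residual-variance estimate from the
   complete-case fit, ``n0`` the number of complete cases and ``q = 2``
   the number of coefficients;
2. draw the coefficients ``beta* ~ N(beta_hat, sigma*^2 (Xo'Xo)^{-1})``;
3. impute ``y_i = beta*_0 + beta*_1 x_i + N(0, sigma*^2)`` for each
   missing slot.

Because the variance is drawn rather than fixed, the posterior predictive
distribution of an imputed value (and of the sum of imputed values in a
dataset) is Student-t with ``n0 - q`` degrees of freedom — heavier-tailed
than normal for small samples, which is exactly what destabilises the
exponential importance weights downstream.

Binary outcome (logistic model): coefficients are drawn from the normal
asymptotic approximation to their posterior, ``beta* ~ N(MLE, I^{-1})``
with ``I`` the observed Fisher information at the MLE, and missing cells
are drawn ``Bernoulli(expit(beta*_0 + beta*_1 x_i))``.

Draw order is fixed per imputation (variance, then coefficients, then
outcome noise) so a seed fully determines the imputation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from ._rng import as_generator
from .datagen import IncompleteSample
from .exceptions import DegenerateDataError, ImputationModelError, ParameterError

__all__ = ["ImputationDraws", "ImputationSet", "impute_normal", "impute_logistic"]

_Q = 2  # intercept + one covariate


@dataclass(frozen=True)
class ImputationDraws:
    """Per-imputation parameter draws.

    ``coef`` has shape (m, 2) — intercept and slope. ``sigma2`` is the
    (m,) vector of residual-variance draws for the normal-linear model and
    ``None`` for the logistic model.
    """

    coef: np.ndarray
    sigma2: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma2 is not None and np.any(self.sigma2 <= 0):
            raise ParameterError("residual-variance draws must be positive")


@dataclass(frozen=True)
class ImputationSet:
    """m completed outcome vectors for one incomplete sample.

    ``completed_y`` has shape (m, n); observed entries are identical
    across rows. ``sums`` holds S_j, the per-imputation sum of imputed
    values over the missing index set — the sole data input to the
    delta-weights.
    """

    completed_y: np.ndarray
    missing_index: np.ndarray
    draws: ImputationDraws
    x: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "completed_y",
                           np.asarray(self.completed_y, dtype=float))
        if self.completed_y.ndim != 2 or self.completed_y.shape[0] < 1:
            raise ParameterError("completed_y must be an (m, n) array with m >= 1")

    @property
    def m(self) -> int:
        return self.completed_y.shape[0]

    @property
    def n(self) -> int:
        return self.completed_y.shape[1]

    @property
    def sums(self) -> np.ndarray:
        """S_j = sum of imputed values in completed dataset j."""
        return self.completed_y[:, self.missing_index].sum(axis=1)

    def head(self, m: int) -> "ImputationSet":
        """The first ``m`` imputations as an ImputationSet (prefix view)."""
        if not 1 <= m <= self.m:
            raise ParameterError("prefix length out of range")
        sigma2 = None if self.draws.sigma2 is None else self.draws.sigma2[:m]
        return ImputationSet(self.completed_y[:m], self.missing_index,
                             ImputationDraws(self.draws.coef[:m], sigma2), self.x)

    def to_frame(self):
        """Long-format table (imputation, row, y)."""
        import pandas as pd

        m, n = self.completed_y.shape
        return pd.DataFrame({
            "imputation": np.repeat(np.arange(m), n),
            "row": np.tile(np.arange(n), m),
            "y": self.completed_y.ravel(),
        })


def _no_missing_copies(sample: IncompleteSample, m: int,
                       coef: np.ndarray, sigma2) -> ImputationSet:
    warnings.warn("sample has no missing outcomes; returning m identical copies",
                  stacklevel=3)
    completed = np.tile(sample.y, (m, 1))
    draws = ImputationDraws(np.tile(coef, (m, 1)),
                            None if sigma2 is None else np.full(m, sigma2))
    return ImputationSet(completed, sample.missing_index, draws, sample.x)


def impute_normal(sample: IncompleteSample, m: int, seed=None) -> ImputationSet:
    """Multiply impute a continuous outcome with Bayesian normal-linear draws."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    obs = sample.observed_index
    mis = sample.missing_index
    n0 = obs.size
    if n0 < _Q + 2:
        raise DegenerateDataError(
            f"need at least {_Q + 2} observed outcomes (got {n0}) so the "
            f"chi-square degrees of freedom n0 - q >= 2")
    x_o = sample.x[obs]
    y_o = sample.y[obs]
    design_o = np.column_stack([np.ones(n0), x_o])
    beta_hat, _, rank, _ = np.linalg.lstsq(design_o, y_o, rcond=None)
    if rank < _Q:
        raise DegenerateDataError("covariate is constant among complete cases")
    resid = y_o - design_o @ beta_hat
    dof = n0 - _Q
    sigma2_hat = float(resid @ resid) / dof
    if sigma2_hat <= 0:
        raise DegenerateDataError("zero residual variance among complete cases")
    xtx_inv = np.linalg.inv(design_o.T @ design_o)
    chol = np.linalg.cholesky(xtx_inv)

    if mis.size == 0:
        return _no_missing_copies(sample, m, beta_hat, sigma2_hat)

    rng = as_generator(seed)
    x_mis = sample.x[mis]
    completed = np.tile(sample.y, (m, 1))
    coef = np.empty((m, _Q))
    sigma2 = np.empty(m)
    for j in range(m):
        sigma2[j] = sigma2_hat * dof / rng.chisquare(dof)
        coef[j] = beta_hat + np.sqrt(sigma2[j]) * (chol @ rng.standard_normal(_Q))
        completed[j, mis] = (coef[j, 0] + coef[j, 1] * x_mis
                             + np.sqrt(sigma2[j]) * rng.standard_normal(mis.size))
    return ImputationSet(completed, mis, ImputationDraws(coef, sigma2), sample.x)


def impute_logistic(sample: IncompleteSample, m: int, seed=None) -> ImputationSet:
    """Multiply impute a binary outcome with asymptotic-posterior logistic draws."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    obs = sample.observed_index
    mis = sample.missing_index
    y_o = sample.y[obs]
    if not np.all(np.isin(y_o, [0.0, 1.0])):
        raise ParameterError("observed outcomes must be 0/1 for logistic imputation")
    if y_o.size < _Q + 1 or y_o.min() == y_o.max():
        raise ImputationModelError(
            "observed outcomes must contain both classes for the logistic "
            "imputation model")
    design_o = np.column_stack([np.ones(obs.size), sample.x[obs]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # surface separation warnings as errors
            fit = sm.Logit(y_o, design_o).fit(disp=0)
    except Exception as err:  # separation, singular information, non-convergence
        raise ImputationModelError(f"logistic imputation model failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise ImputationModelError("logistic imputation model did not converge")
    mle = np.asarray(fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ImputationModelError("singular information matrix") from err

    if mis.size == 0:
        return _no_missing_copies(sample, m, mle, None)

    rng = as_generator(seed)
    x_mis = sample.x[mis]
    completed = np.tile(sample.y, (m, 1))
    coef = np.empty((m, _Q))
    for j in range(m):
        coef[j] = mle + chol @ rng.standard_normal(_Q)
        p = expit(coef[j, 0] + coef[j, 1] * x_mis)
        completed[j, mis] = (rng.random(mis.size) < p).astype(float)
    return ImputationSet(completed, mis, ImputationDraws(coef, None), sample.x)
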