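"""Synthetic data generation under a logistic selection model.

Two generative models are provided. The continuous model draws pairs
(X, Y) from a bivariate normal distribution; the binary model draws a
normal covariate X and a Bernoulli outcome with
``logit P(Y=1) = phi0 + phi1*X``. Missingness is then imposed on the
outcome through the logistic selection model

    logit P(R = 1 | X, Y) = alpha + gamma*X + delta*Y,

where ``R = 1`` means Y is observed. ``delta`` is the sensitivity
parameter: ``delta = 0`` makes the mechanism missing-at-random given X,
and any other value makes missingness depend on the (possibly
unobserved) outcome itself, i.e. missing-not-at-random.

The predictability of missingness from (X, Y) is quantified with a
rank-based AUROC of a logistic model of R on both variables, fitted to
the pre-deletion data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from ._rng import as_generator
from .exceptions import DegenerateDataError, ParameterError

__all__ = [
    "ContinuousPopulation",
    "BinaryPopulation",
    "MissingnessModel",
    "CompleteSample",
    "IncompleteSample",
    "generate_continuous",
    "generate_binary",
    "apply_mnar",
    "missingness_auroc",
    "write_sample_csv",
    "read_sample_csv",
]


@dataclass(frozen=True)
class ContinuousPopulation:
    """Bivariate-normal population for (X, Y).

    The implied regression of Y on X has slope
    ``correlation * sqrt(var_y / var_x)`` and residual variance
    ``var_y * (1 - correlation**2)``.
    """

    mean_x: float = 0.0
    mean_y: float = 0.0
    var_x: float = 1.0
    var_y: float = 1.0
    correlation: float = 0.5

    def __post_init__(self):
        if not (self.var_x > 0 and self.var_y > 0):
            raise ParameterError("variances must be positive")
        if not abs(self.correlation) < 1:
            raise ParameterError("|correlation| must be < 1")
        if not np.all(np.isfinite([self.mean_x, self.mean_y, self.var_x,
                                   self.var_y, self.correlation])):
            raise ParameterError("population parameters must be finite")

    @property
    def slope(self) -> float:
        """True regression slope of Y on X."""
        return self.correlation * np.sqrt(self.var_y / self.var_x)

    @property
    def intercept(self) -> float:
        return self.mean_y - self.slope * self.mean_x

    @property
    def residual_variance(self) -> float:
        return self.var_y * (1.0 - self.correlation ** 2)


@dataclass(frozen=True)
class BinaryPopulation:
    """Normal covariate with a Bernoulli outcome, logit P(Y=1) = phi0 + phi1*X.

    With ``phi0 = 0`` and a symmetric covariate the marginal proportion
    P(Y=1) equals 0.5 exactly, which makes the canonical scenario's truth
    easy to state.
    """

    phi0: float = 0.0
    phi1: float = 0.5
    mean_x: float = 0.0
    var_x: float = 1.0

    def __post_init__(self):
        if not self.var_x > 0:
            raise ParameterError("var_x must be positive")
        if not np.all(np.isfinite([self.phi0, self.phi1, self.mean_x, self.var_x])):
            raise ParameterError("population parameters must be finite")


@dataclass(frozen=True)
class MissingnessModel:
    """Logistic selection model logit P(R=1|X,Y) = alpha + gamma*X + delta_gen*Y."""

    alpha: float
    gamma: float
    delta_gen: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.alpha, self.gamma, self.delta_gen])):
            raise ParameterError("missingness parameters must be finite")

    def observation_probability(self, x, y):
        return expit(self.alpha + self.gamma * np.asarray(x)
                     + self.delta_gen * np.asarray(y))


@dataclass(frozen=True)
class CompleteSample:
    """Fully observed (x, y) pairs."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ParameterError("x and y must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ParameterError("complete sample must not contain missing values")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class IncompleteSample:
    """(x, y) pairs with the outcome partially observed.

    ``y`` is a float vector with NaN where the outcome is missing and
    ``r`` the 0/1 observation indicator (1 = observed, matching the
    selection-model convention). The covariate is always fully observed.
    """

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=int))
        if not (self.x.shape == self.y.shape == self.r.shape) or self.x.ndim != 1:
            raise ParameterError("x, y, r must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.x)):
            raise ParameterError("covariate must be fully observed")
        if not np.all(np.isin(self.r, [0, 1])):
            raise ParameterError("r must be a 0/1 indicator")
        if not np.array_equal(np.isnan(self.y), self.r == 0):
            raise ParameterError("y must be missing exactly where r == 0")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def n_observed(self) -> int:
        return int(self.r.sum())

    @property
    def n_missing(self) -> int:
        return int(self.n - self.r.sum())

    @property
    def observed_index(self) -> np.ndarray:
        return np.flatnonzero(self.r == 1)

    @property
    def missing_index(self) -> np.ndarray:
        """I_Y, the index set of subjects with the outcome missing."""
        return np.flatnonzero(self.r == 0)

    @property
    def is_degenerate(self) -> bool:
        """True when downstream imputation/analysis guards will refuse this
        sample (fewer than 2 observed or no missing outcomes)."""
        return self.n_observed < 2 or self.n_missing < 1


def generate_continuous(pop: ContinuousPopulation, n: int, seed=None) -> CompleteSample:
    """Draw ``n`` (x, y) pairs from the bivariate-normal population."""
    if n < 2:
        raise ParameterError("n must be at least 2")
    rng = as_generator(seed)
    cov_xy = pop.correlation * np.sqrt(pop.var_x * pop.var_y)
    cov = np.array([[pop.var_x, cov_xy], [cov_xy, pop.var_y]])
    xy = rng.multivariate_normal([pop.mean_x, pop.mean_y], cov, size=n)
    return CompleteSample(x=xy[:, 0], y=xy[:, 1])


def generate_binary(pop: BinaryPopulation, n: int, seed=None) -> CompleteSample:
    """Draw ``n`` pairs with a normal covariate and a logistic binary outcome.

    Draw order contract: ``x`` first (one ``standard_normal(n)`` call),
    then one ``random(n)`` call of uniforms compared against
    ``expit(phi0 + phi1*x)``.
    """
    if n < 2:
        raise ParameterError("n must be at least 2")
    rng = as_generator(seed)
    x = pop.mean_x + np.sqrt(pop.var_x) * rng.standard_normal(n)
    p = expit(pop.phi0 + pop.phi1 * x)
    y = (rng.random(n) < p).astype(float)
    return CompleteSample(x=x, y=y)


def apply_mnar(sample: CompleteSample, model: MissingnessModel, seed=None) -> IncompleteSample:
    """Impose MNAR missingness on the outcome via the logistic selection model.

    Each subject is observed independently with probability
    ``expit(alpha + gamma*x_i + delta_gen*y_i)``. The draw is one
    ``rng.random(n)`` call compared elementwise against these
    probabilities, so a fixed seed fully determines the mask. All-missing
    or all-observed outcomes are allowed here (the achieved missingness
    fraction is stochastic); downstream guards flag them via
    :attr:`IncompleteSample.is_degenerate`.
    """
    rng = as_generator(seed)
    p_obs = model.observation_probability(sample.x, sample.y)
    r = (rng.random(sample.n) < p_obs).astype(int)
    y = np.where(r == 1, sample.y, np.nan)
    return IncompleteSample(x=sample.x, y=y, r=r)


def missingness_auroc(sample: CompleteSample, r) -> float:
    """AUROC of a logistic model of the observation indicator on (x, y).

    The model is fitted on the pre-deletion data (both outcome components
    available), and the AUROC is the rank-based (Mann-Whitney,
    tie-averaged) area for the fitted probabilities against ``r``. IRLS
    (GLM-Binomial) is used so that perfectly separable indicators return
    AUROC 1.0 instead of raising: the fitted ranks are already correct
    when the MLE diverges.
    """
    r = np.asarray(r, dtype=int)
    if r.shape != sample.x.shape:
        raise ParameterError("r must align with the sample")
    if r.min() == r.max():
        raise DegenerateDataError("indicator has a single class; AUROC undefined")
    design = sm.add_constant(np.column_stack([sample.x, sample.y]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = sm.GLM(r, design, family=sm.families.Binomial()).fit()
        probs = np.asarray(fitted.fittedvalues)
    return float(roc_auc_score(r, probs))


def write_sample_csv(sample: IncompleteSample, path) -> None:
    """Write a sample as CSV with columns x, y, r; missing y as empty field."""
    frame = pd.DataFrame({"x": sample.x, "y": sample.y, "r": sample.r})
    frame.to_csv(path, index=False, na_rep="")


def read_sample_csv(path) -> IncompleteSample:
    """Read a sample written by :func:`write_sample_csv`.

    The ``r`` column is optional; if absent it is inferred from which
    ``y`` cells are empty.
    """
    frame = pd.read_csv(path)
    if "x" not in frame or "y" not in frame:
        raise ParameterError("sample CSV requires 'x' and 'y' columns")
    y = frame["y"].to_numpy(dtype=float)
    if "r" in frame:
        r = frame["r"].to_numpy(dtype=int)
    else:
        r = (~np.isnan(y)).astype(int)
    return IncompleteSample(x=frame["x"].to_numpy(dtype=float), y=y, r=r)
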