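"""Scenario-driven Monte-Carlo evaluation of the weighting approach.

A :class:`Scenario` bundles the generative model (continuous or binary
outcome), the logistic selection-model parameters, the analysis delta, the
imputation counts and replicate count. :func:`run_replicate` executes one
replicate end to end — generate, analyse the full data, impose MNAR
deletion, complete-case analysis, multiple imputation, Rubin (MAR) and
delta-weighted (MNAR) pooling for every requested m — and
:func:`run_scenario` aggregates replicates into method x m x estimand mean
estimates with Monte-Carlo standard errors and the mean missingness AUROC.

Seeding: replicate i of a study with master seed s always draws from
``SeedSequence(s, spawn_key=(i,))``, split into three child streams
(generation, deletion, imputation), so any replicate is regenerable in
isolation and results do not depend on execution order.

Within a replicate, the imputation set is drawn once at ``max(m_list)``
and smaller m use its leading prefix; comparisons across m are therefore
paired within replicate.

Canonical scenarios (n = 100, 1000 replicates, ~50% outcome missingness):

- continuous, large MNAR:    alpha=0,    gamma=1,   delta=1
- continuous, moderate MNAR: alpha=0,    gamma=0.8, delta=0.5
- binary, large MNAR:        alpha=-0.4, gamma=1,   delta=1
- binary, moderate MNAR:     alpha=-0.1, gamma=1,   delta=0.5
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import replicate_seed
from . import datagen
from .datagen import (BinaryPopulation, ContinuousPopulation, MissingnessModel,
                      apply_mnar, generate_binary, generate_continuous,
                      missingness_auroc)
from .estimands import analyze, complete_case, default_estimands
from .exceptions import (AnalysisError, DegenerateDataError,
                         ImputationModelError, MisensError, ParameterError,
                         StudyError)
from .impute import impute_logistic, impute_normal
from .pooling import delta_weights, mnar_pool, rubin_pool

__all__ = ["Scenario", "ReplicateResult", "ScenarioResults", "run_replicate",
           "run_scenario", "load_scenario", "REDUCED_N_SIMS", "REDUCED_M_LIST"]

logger = logging.getLogger(__name__)

#: reduced-mode defaults for quick runs
REDUCED_N_SIMS = 200
REDUCED_M_LIST = (5, 10, 50)

#: the imputation counts used in the full evaluation
FULL_M_LIST = (5, 10, 50, 100, 500, 1000)


@dataclass(frozen=True)
class Scenario:
    """One simulation-study configuration.

    ``delta_analysis`` defaults to ``delta_gen`` — the known-delta setting
    in which the weighting approach is evaluated under the best possible
    conditions. ``m_list`` may be empty to skip imputation entirely
    (full-data, complete-case and AUROC summaries only).
    """

    outcome_type: str  # "continuous" | "binary"
    n: int
    alpha: float
    gamma: float
    delta_gen: float
    delta_analysis: float | None = None
    m_list: tuple[int, ...] = REDUCED_M_LIST
    n_sims: int = REDUCED_N_SIMS
    seed: int = 0
    estimands: tuple[str, ...] | None = None
    correlation: float = 0.5   # continuous model
    phi0: float = 0.0          # binary model
    phi1: float = 0.5

    def __post_init__(self):
        if self.outcome_type not in ("continuous", "binary"):
            raise ParameterError("outcome_type must be 'continuous' or 'binary'")
        if self.n < 4:
            raise ParameterError("n must be at least 4")
        if any(m < 2 for m in self.m_list):
            raise ParameterError("all imputation counts must be >= 2")
        object.__setattr__(self, "m_list", tuple(int(m) for m in self.m_list))
        if self.delta_analysis is None:
            object.__setattr__(self, "delta_analysis", float(self.delta_gen))
        if self.estimands is None:
            object.__setattr__(self, "estimands",
                               default_estimands(self.outcome_type))
        else:
            object.__setattr__(self, "estimands", tuple(self.estimands))

    @property
    def population(self):
        if self.outcome_type == "continuous":
            return ContinuousPopulation(correlation=self.correlation)
        return BinaryPopulation(phi0=self.phi0, phi1=self.phi1)

    @property
    def missingness(self) -> MissingnessModel:
        return MissingnessModel(self.alpha, self.gamma, self.delta_gen)

    def reduced(self) -> "Scenario":
        """Copy with the reduced replicate count and imputation counts."""
        m_list = tuple(m for m in self.m_list if m in REDUCED_M_LIST) or REDUCED_M_LIST
        return replace(self, n_sims=REDUCED_N_SIMS, m_list=m_list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReplicateResult:
    """Per-method estimates from a single replicate."""

    replicate_id: int
    failed: str | None = None
    auroc: float | None = None
    # list of dicts: method, m (None for full/cc), estimand, estimate, se
    records: list = field(default_factory=list)
    # per-m maximum normalised weight
    max_weight: dict = field(default_factory=dict)

    def estimate(self, method: str, estimand: str, m: int | None = None) -> float:
        for rec in self.records:
            if (rec["method"] == method and rec["estimand"] == estimand
                    and rec["m"] == m):
                return rec["estimate"]
        raise KeyError((method, estimand, m))


def _generate(scenario: Scenario, rng) -> datagen.CompleteSample:
    if scenario.outcome_type == "continuous":
        return generate_continuous(scenario.population, scenario.n, rng)
    return generate_binary(scenario.population, scenario.n, rng)


def run_replicate(scenario: Scenario, replicate_id: int) -> ReplicateResult:
    """Execute one replicate; module errors are captured, never raised."""
    gen_seed, del_seed, imp_seed = replicate_seed(
        scenario.seed, replicate_id).spawn(3)
    result = ReplicateResult(replicate_id)
    impute = (impute_normal if scenario.outcome_type == "continuous"
              else impute_logistic)
    try:
        complete = _generate(scenario, np.random.default_rng(gen_seed))
        for estimand in scenario.estimands:
            est = analyze(complete.y, complete.x, estimand)
            result.records.append({"method": "full", "m": None,
                                   "estimand": estimand,
                                   "estimate": est.estimate, "se": est.se})
        incomplete = apply_mnar(complete, scenario.missingness,
                                np.random.default_rng(del_seed))
        result.auroc = missingness_auroc(complete, incomplete.r)
        for estimand in scenario.estimands:
            est = complete_case(incomplete, estimand)
            result.records.append({"method": "complete_case", "m": None,
                                   "estimand": estimand,
                                   "estimate": est.estimate, "se": est.se})
        if scenario.m_list:
            m_max = max(scenario.m_list)
            imps = impute(incomplete, m_max, np.random.default_rng(imp_seed))
            per_imp = {estimand: [analyze(imps.completed_y[j], incomplete.x,
                                          estimand)
                                  for j in range(m_max)]
                       for estimand in scenario.estimands}
            for m in scenario.m_list:
                weights = delta_weights(imps.sums[:m], scenario.delta_analysis)
                result.max_weight[m] = weights.max_weight
                for estimand in scenario.estimands:
                    head = per_imp[estimand][:m]
                    mar = rubin_pool(head, estimand=estimand)
                    mnar = mnar_pool(head, weights, estimand=estimand)
                    result.records.append(
                        {"method": "mi_mar", "m": m, "estimand": estimand,
                         "estimate": mar.estimate, "se": mar.se})
                    result.records.append(
                        {"method": "mnar_weighted", "m": m, "estimand": estimand,
                         "estimate": mnar.estimate, "se": mnar.se})
    except (AnalysisError, DegenerateDataError, ImputationModelError) as err:
        result.failed = f"{type(err).__name__}: {err}"
        result.records = []
        result.max_weight = {}
        logger.debug("replicate %d failed: %s", replicate_id, result.failed)
    return result


@dataclass
class ScenarioResults:
    """Aggregated study output.

    ``summary`` is a tidy table (method, m, estimand, mean_estimate, mc_se,
    n_reps); ``replicates`` the replicate-level table; ``max_weight`` the
    per-m mean of the maximum normalised weight across replicates.
    """

    scenario: Scenario
    summary: pd.DataFrame
    replicates: pd.DataFrame
    mean_auroc: float
    n_failed: int
    failures: list

    def mean_estimate(self, method: str, estimand: str,
                      m: int | None = None) -> float:
        tab = self.summary
        mask = (tab["method"] == method) & (tab["estimand"] == estimand)
        mask &= tab["m"].isna() if m is None else (tab["m"] == m)
        rows = tab[mask]
        if len(rows) != 1:
            raise KeyError((method, estimand, m))
        return float(rows["mean_estimate"].iloc[0])

    def mc_se(self, method: str, estimand: str, m: int | None = None) -> float:
        tab = self.summary
        mask = (tab["method"] == method) & (tab["estimand"] == estimand)
        mask &= tab["m"].isna() if m is None else (tab["m"] == m)
        return float(tab[mask]["mc_se"].iloc[0])

    def mnar_series(self, estimand: str) -> pd.DataFrame:
        """Mean MNAR estimate against m (for the estimate-vs-m figures)."""
        tab = self.summary
        rows = tab[(tab["method"] == "mnar_weighted")
                   & (tab["estimand"] == estimand)].sort_values("m")
        return rows[["m", "mean_estimate", "mc_se"]].reset_index(drop=True)

    @property
    def max_weight(self) -> pd.Series:
        """Mean (over replicates) of the per-replicate max normalised weight."""
        tab = self.replicates
        rows = tab[tab["method"] == "max_weight"]
        return rows.groupby("m")["estimate"].mean()

    def plot_mnar_vs_m(self, estimand: str, ax=None, truth: float | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        series = self.mnar_series(estimand)
        ax.plot(series["m"], series["mean_estimate"], marker="o", color="black")
        if truth is not None:
            ax.axhline(truth, linestyle="--", color="grey", label="true value")
            ax.legend(loc="best", fontsize="small")
        ax.set_xscale("log")
        ax.set_xlabel("number of imputations (log scale)")
        ax.set_ylabel(f"mean MNAR estimate: {estimand}")
        return ax

    def save(self, out_dir) -> None:
        """Write results.csv, replicates.csv and a JSON run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "results.csv", index=False)
        self.replicates.to_csv(out / "replicates.csv", index=False)
        manifest = {
            "scenario": self.scenario.to_dict(),
            "mean_auroc": self.mean_auroc,
            "n_failed": self.n_failed,
            "failures": self.failures,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_scenario(scenario: Scenario,
                 max_failed_fraction: float = 0.10) -> ScenarioResults:
    """Run all replicates of a scenario and aggregate."""
    if scenario.n_sims < 2:
        raise StudyError("n_sims must be at least 2")
    rows = []
    aurocs = []
    failures = []
    for rep in range(scenario.n_sims):
        logger.debug("replicate %d/%d", rep + 1, scenario.n_sims)
        res = run_replicate(scenario, rep)
        if res.failed is not None:
            failures.append({"replicate": rep, "reason": res.failed})
            continue
        aurocs.append(res.auroc)
        for rec in res.records:
            rows.append({"replicate": rep, **rec})
        for m, w in res.max_weight.items():
            rows.append({"replicate": rep, "method": "max_weight", "m": m,
                         "estimand": "max_weight", "estimate": w, "se": np.nan})
    n_failed = len(failures)
    if n_failed > max_failed_fraction * scenario.n_sims:
        raise StudyError(
            f"{n_failed}/{scenario.n_sims} replicates failed "
            f"(> {max_failed_fraction:.0%}); first failures: {failures[:5]}")
    replicates = pd.DataFrame(rows)
    grouped = (replicates[replicates["method"] != "max_weight"]
               .groupby(["method", "m", "estimand"], dropna=False)["estimate"])
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    summary["mc_se"] = summary["std"] / np.sqrt(summary["count"])
    summary = summary.rename(columns={"mean": "mean_estimate",
                                      "count": "n_reps"})
    summary = summary[["method", "m", "estimand", "mean_estimate", "mc_se",
                       "n_reps"]]
    return ScenarioResults(scenario, summary, replicates,
                           float(np.mean(aurocs)), n_failed, failures)


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML or JSON configuration file.

    Recognised keys: outcome_type, n, alpha, gamma, delta_gen and the
    optional delta_analysis, m_list, n_sims, seed, estimands, correlation,
    phi0, phi1.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        import yaml

        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ParameterError("scenario config must be a mapping")
    allowed = {"outcome_type", "n", "alpha", "gamma", "delta_gen",
               "delta_analysis", "m_list", "n_sims", "seed", "estimands",
               "correlation", "phi0", "phi1"}
    unknown = set(config) - allowed
    if unknown:
        raise ParameterError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("m_list", "estimands"):
        if key in config and config[key] is not None:
            config[key] = tuple(config[key])
    return Scenario(**config)
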