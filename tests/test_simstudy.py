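"""Monte-Carlo scenario machinery: replicates, aggregation, configs."""

import json

import numpy as np
import pytest
from scipy import stats

from misens import (ParameterError, Scenario, StudyError, analyze, apply_mnar,
                    complete_case, delta_weights, generate_continuous,
                    impute_normal, missingness_auroc, mnar_pool, rubin_pool,
                    run_replicate, run_scenario)
from misens._rng import replicate_seed
from misens.simstudy import load_scenario


@pytest.fixture(scope="module")
def small_scenario():
    return Scenario("continuous", n=60, alpha=0.0, gamma=1.0, delta_gen=0.5,
                    m_list=(5, 10), n_sims=20, seed=101)


@pytest.fixture(scope="module")
def small_results(small_scenario):
    return run_scenario(small_scenario)


class TestScenario:
    def test_delta_analysis_defaults_to_generating_value(self):
        sc = Scenario("continuous", 50, 0.0, 1.0, 0.7)
        assert sc.delta_analysis == 0.7

    def test_estimands_default_by_outcome_type(self):
        assert Scenario("continuous", 50, 0, 1, 1).estimands == (
            "marginal_mean", "linear_slope")
        assert Scenario("binary", 50, 0, 1, 1).estimands == (
            "marginal_proportion", "logistic_slope")

    def test_invalid_configuration(self):
        with pytest.raises(ParameterError):
            Scenario("count", 50, 0, 1, 1)
        with pytest.raises(ParameterError):
            Scenario("continuous", 50, 0, 1, 1, m_list=(1,))

    def test_reduced_mode(self):
        sc = Scenario("continuous", 100, 0, 1, 1,
                      m_list=(5, 10, 50, 100, 500, 1000), n_sims=1000)
        red = sc.reduced()
        assert red.n_sims == 200
        assert red.m_list == (5, 10, 50)
        assert red.delta_analysis == sc.delta_analysis


class TestRunReplicate:
    def test_deterministic_rerun(self, small_scenario):
        a = run_replicate(small_scenario, 3)
        b = run_replicate(small_scenario, 3)
        assert a.records == b.records
        assert a.auroc == b.auroc
        assert a.max_weight == b.max_weight

    def test_matches_manual_module_chain(self, small_scenario):
        """The replicate must be exactly the documented chain of module calls
        with the documented per-replicate seed streams."""
        sc = small_scenario
        rep = run_replicate(sc, 5)
        gen, dele, imp = replicate_seed(sc.seed, 5).spawn(3)
        sample = generate_continuous(sc.population, sc.n,
                                     np.random.default_rng(gen))
        incomplete = apply_mnar(sample, sc.missingness,
                                np.random.default_rng(dele))
        assert rep.auroc == pytest.approx(
            missingness_auroc(sample, incomplete.r), abs=1e-14)
        full = analyze(sample.y, sample.x, "marginal_mean")
        assert rep.estimate("full", "marginal_mean") == full.estimate
        cc = complete_case(incomplete, "linear_slope")
        assert rep.estimate("complete_case", "linear_slope") == cc.estimate
        imps = impute_normal(incomplete, max(sc.m_list),
                             np.random.default_rng(imp))
        for m in sc.m_list:
            ests = [analyze(imps.completed_y[j], incomplete.x, "marginal_mean")
                    for j in range(m)]
            w = delta_weights(imps.sums[:m], sc.delta_analysis)
            assert rep.estimate("mi_mar", "marginal_mean", m) == pytest.approx(
                rubin_pool(ests).estimate, abs=1e-14)
            assert rep.estimate("mnar_weighted", "marginal_mean", m) == pytest.approx(
                mnar_pool(ests, w).estimate, abs=1e-14)
            assert rep.max_weight[m] == pytest.approx(w.max_weight, abs=1e-14)

    def test_mar_generation_makes_mnar_equal_mi(self):
        sc = Scenario("continuous", n=60, alpha=0.0, gamma=1.0, delta_gen=0.0,
                      m_list=(5,), n_sims=4, seed=55)
        assert sc.delta_analysis == 0.0
        for rep_id in range(sc.n_sims):
            rep = run_replicate(sc, rep_id)
            for estimand in sc.estimands:
                assert rep.estimate("mnar_weighted", estimand, 5) == pytest.approx(
                    rep.estimate("mi_mar", estimand, 5), abs=1e-12)


class TestRunScenario:
    def test_summary_layout(self, small_results, small_scenario):
        tab = small_results.summary
        assert set(tab.columns) == {"method", "m", "estimand", "mean_estimate",
                                    "mc_se", "n_reps"}
        # full and complete-case rows carry no m
        assert tab[tab["method"].isin(["full", "complete_case"])]["m"].isna().all()
        assert (tab["mc_se"] >= 0).all()
        methods = set(tab["method"])
        assert methods == {"full", "complete_case", "mi_mar", "mnar_weighted"}
        for m in small_scenario.m_list:
            assert small_results.mean_estimate("mi_mar", "marginal_mean", m)

    def test_weighted_estimate_within_per_replicate_mar_range(self, small_scenario):
        """First importance-sampling condition, end to end: in every
        replicate the weighted estimate lies inside the range of the
        per-imputation estimates."""
        sc = small_scenario
        for rep_id in range(10):
            gen, dele, imp = replicate_seed(sc.seed, rep_id).spawn(3)
            sample = generate_continuous(sc.population, sc.n,
                                         np.random.default_rng(gen))
            incomplete = apply_mnar(sample, sc.missingness,
                                    np.random.default_rng(dele))
            imps = impute_normal(incomplete, max(sc.m_list),
                                 np.random.default_rng(imp))
            rep = run_replicate(sc, rep_id)
            for m in sc.m_list:
                theta = np.array([analyze(imps.completed_y[j], incomplete.x,
                                          "marginal_mean").estimate
                                  for j in range(m)])
                est = rep.estimate("mnar_weighted", "marginal_mean", m)
                assert theta.min() - 1e-12 <= est <= theta.max() + 1e-12

    def test_mnar_distribution_heavier_tailed_at_large_m(self):
        """Replicate-level MNAR estimates grow heavier tails as m grows and
        the weights concentrate: the maximum normalised weight stays of
        order one instead of decaying like the uniform level 1/m, so the
        concentration relative to uniform weighting explodes with m. The
        MAR estimates stay stable across m throughout."""
        sc = Scenario("continuous", n=100, alpha=0.0, gamma=1.0, delta_gen=1.0,
                      m_list=(5, 1000), n_sims=500, seed=2024,
                      estimands=("marginal_mean",))
        out = run_scenario(sc)
        reps = out.replicates
        mnar = reps[reps["method"] == "mnar_weighted"]
        kurt_small = stats.kurtosis(mnar[mnar["m"] == 5]["estimate"])
        kurt_large = stats.kurtosis(mnar[mnar["m"] == 1000]["estimate"])
        assert kurt_large > kurt_small
        # concentration relative to the uniform level 1/m grows with m,
        # and at m=1000 one imputation still holds most of the weight
        maxw = out.max_weight
        assert 1000 * maxw[1000] > 5 * maxw[5]
        assert maxw[1000] > 100 * (1 / 1000)
        # MAR estimates essentially constant across m
        mi5 = out.mean_estimate("mi_mar", "marginal_mean", 5)
        mi1000 = out.mean_estimate("mi_mar", "marginal_mean", 1000)
        pooled_se = np.hypot(out.mc_se("mi_mar", "marginal_mean", 5),
                             out.mc_se("mi_mar", "marginal_mean", 1000))
        assert abs(mi5 - mi1000) <= 3 * pooled_se

    def test_failed_replicates_counted_and_capped(self):
        # tiny binary samples: complete-case and imputation guards trip often
        sc = Scenario("binary", n=12, alpha=-1.5, gamma=1.0, delta_gen=1.0,
                      m_list=(2,), n_sims=40, seed=77)
        out = run_scenario(sc, max_failed_fraction=1.0)
        assert out.n_failed > 0
        assert len(out.failures) == out.n_failed
        with pytest.raises(StudyError):
            run_scenario(sc, max_failed_fraction=0.0)

    def test_save_writes_results_and_manifest(self, tmp_path, small_results):
        small_results.save(tmp_path)
        assert (tmp_path / "results.csv").exists()
        assert (tmp_path / "replicates.csv").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["scenario"]["n"] == 60
        assert manifest["n_failed"] == small_results.n_failed

    def test_mnar_series_and_plot(self, small_results):
        series = small_results.mnar_series("marginal_mean")
        assert list(series["m"]) == [5, 10]
        import matplotlib.pyplot as plt

        ax = small_results.plot_mnar_vs_m("marginal_mean", truth=0.0)
        plt.close(ax.figure)


class TestLoadScenario:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "outcome_type: continuous\nn: 100\nalpha: 0.0\ngamma: 1.0\n"
            "delta_gen: 1.0\nseed: 9\nm_list: [5, 10]\nn_sims: 50\n")
        sc = load_scenario(path)
        assert sc.outcome_type == "continuous"
        assert sc.m_list == (5, 10)
        assert sc.delta_analysis == 1.0

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "scenario.json"
        path.write_text(json.dumps({
            "outcome_type": "binary", "n": 80, "alpha": -0.4, "gamma": 1.0,
            "delta_gen": 1.0, "seed": 3}))
        sc = load_scenario(path)
        assert sc.outcome_type == "binary"
        assert sc.estimands == ("marginal_proportion", "logistic_slope")

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({
            "outcome_type": "binary", "n": 80, "alpha": 0.0, "gamma": 1.0,
            "delta_gen": 1.0, "bogus": 1}))
        with pytest.raises(ParameterError):
            load_scenario(path)
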