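# misens

Sensitivity analysis for multiple imputation when the outcome may be
**missing not at random (MNAR)**, via selection-model importance
reweighting of the imputations — together with the diagnostics that reveal
when the reweighting breaks down, and a Monte-Carlo framework for studying
exactly how it breaks down.

## The problem

Multiple imputation (MI), as implemented in standard software, assumes the
outcome is missing at random (MAR): given the observed data, missingness
does not depend on the unobserved values. That assumption cannot be checked
from the data, so a responsible analysis asks how the conclusions move as
the mechanism departs from MAR.

For a partially observed outcome Y, a fully observed covariate X, and the
observation indicator R (1 = observed), the departure is parameterised by a
logistic selection model

```
logit P(R = 1 | X, Y) = f(X) + δY .
```

δ is the log-odds change in the probability of *observing* Y per unit of
Y, holding X fixed; δ = 0 is MAR. Given m imputed datasets drawn under
MAR, with per-imputation estimates θ̂ⱼ and standard errors, the MAR
combination uses Rubin's rules

```
θ̂ᴹᴬᴿ = (1/m) Σⱼ θ̂ⱼ ,      V = V_W + (1 + 1/m) V_B .
```

The MNAR analysis reweights the same estimates by the importance weights

```
w̃ⱼ(δ) = exp(−δ Σ_{i∈I_Y} Y_{ij}) ,      wⱼ(δ) = w̃ⱼ / Σₖ w̃ₖ ,
```

where the sum runs over the imputed cells of dataset j, giving

```
θ̂ᴹᴺᴬᴿ(δ) = Σⱼ wⱼ(δ) θ̂ⱼ
```

with weighted within/between variance components. For δ > 0 the
imputations with the smallest sums of imputed values are up-weighted.

The catch — and the reason this package includes a full simulation-study
module — is that proper imputation draws the residual variance from its
posterior, so the sum of imputed values is Student-t distributed, while the
weights are exponential in that sum. The importance ratio is unbounded:
as m grows, a single extreme imputation eventually captures nearly all the
weight and the weighted estimate drifts and destabilises rather than
converging. `misens` implements the estimator faithfully, the graphical
weight diagnostics, the grid-search rules for a plausible δ range (maximum
normalised weight ≤ 0.5, at least five weights ≥ 1/m), and the
scenario-driven evaluation that exhibits the failure quantitatively.

## Who this is for

Biostatisticians and epidemiologists running MNAR sensitivity analyses
after MI with a single incomplete outcome, and methodologists studying the
behaviour of importance-reweighted MI estimators.

## Worked example

Generate a study dataset (n = 500, bivariate-normal (X, Y) with
correlation 0.5, outcome deleted through the selection model with
α = 0.12, γ = 1, δ = 0.2 — about half the outcomes missing), then run the
sensitivity analysis at the generating δ:

```python
from misens import (ContinuousPopulation, MissingnessModel, MNARSensitivity,
                    apply_mnar, generate_continuous, write_sample_csv)

sample = generate_continuous(ContinuousPopulation(correlation=0.5), 500, seed=42)
incomplete = apply_mnar(sample,
                        MissingnessModel(alpha=0.12, gamma=1.0, delta_gen=0.2),
                        seed=43)
write_sample_csv(incomplete, "study.csv")

model = MNARSensitivity.from_csv("study.csv")
results = model.fit(m=300, delta=0.2, seed=7)
print(results.summary())
```

```
Delta-weighting MNAR sensitivity analysis
=============================================================
outcome type: continuous    n: 500  observed: 283  missing: 217
imputations (m): 300    delta: 0.2    max weight: 0.917    ESS: 1.2
-------------------------------------------------------------
estimand             method           estimate       se           95% CI
-------------------------------------------------------------
marginal_mean        complete case       0.202    0.050 [ 0.103,  0.300]
marginal_mean        MI (MAR)            0.062    0.053 [-0.041,  0.165]
marginal_mean        MNAR weighted      -0.063    0.043 [-0.147,  0.021]
linear_slope         complete case       0.366    0.047 [ 0.274,  0.458]
linear_slope         MI (MAR)            0.365    0.045 [ 0.277,  0.452]
linear_slope         MNAR weighted       0.407    0.035 [ 0.339,  0.474]
-------------------------------------------------------------
MNAR variance uses weighted within/between components; CIs use a normal reference.
```

Reading the output: the true marginal mean is 0 and the true slope 0.5
(this dataset's full-data mean was −0.003 before deletion). Complete-case
analysis overstates the mean (0.202) because high-Y subjects are more
likely to be observed; MI under MAR removes only the X-explained part of
that bias (0.062); reweighting with the true δ moves both estimands
further toward the full-data values (−0.063 and 0.407). But note the
header: one imputation out of 300 carries 92% of the weight (effective
sample size 1.2 of 300) — exactly the degeneracy the diagnostics are
there to expose, and the reason the weighted estimate overshoots as m
grows. `results.plot_weights()` and `results.plot_running()` draw the two
diagnostic plots; `results.select_delta_range()` applies the two graphical
rules on a δ grid (here it returns (−0.49, 0.11), driven by the same
dominant weight).

The same analysis from a shell:

```sh
misens analyze --data study.csv --m 300 --delta 0.2 --seed 7 --plot diag.png
misens delta-range --data study.csv --m 300 --grid -2:2:0.01 --seed 7
misens simulate --config scenario.yaml --out results/ --full
```

## Monte-Carlo evaluation

`misens.simstudy` runs full scenario evaluations: generate a complete
sample, analyse it, impose MNAR deletion, run complete-case analysis, MI
under MAR and the δ-weighted analysis for each imputation count, and
aggregate means and Monte-Carlo standard errors over replicates. The
canonical scenarios (n = 100, 1000 replicates, ≈50% missingness, δ of 0.5
or 1) show the signature behaviour: MAR-MI estimates are stable in m while
the weighted MNAR estimates drift monotonically with m and do not converge
to the truth.

```python
from misens import Scenario, run_scenario

study = run_scenario(Scenario("continuous", n=100, alpha=0.0, gamma=1.0,
                              delta_gen=1.0, m_list=(5, 10, 50), n_sims=200,
                              seed=0))
print(study.summary)
```

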