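# Methods

## Model and estimator

Let Y be a partially observed outcome, X a fully observed covariate, and
R the observation indicator (R = 1 when Y is observed). The package works
within the selection-model factorisation
f(Y, R | X) = f(R | Y, X) · f(Y | X) with a logistic missingness model

    logit P(R = 1 | X, Y) = α + γX + δY.

δ is the sensitivity parameter: the log-odds change in the probability of
observing Y per unit of Y at fixed X. δ = 0 is MAR given X; δ cannot be
estimated from the incomplete data and must be supplied (or ranged over)
by the analyst.

The analysis pipeline is: (1) multiply impute Y under MAR with proper
Bayesian draws; (2) compute the target analysis on each completed dataset;
(3) pool with Rubin's rules for the MAR answer; (4) reweight the same
per-imputation estimates with the importance weights

    w̃_j(δ) = exp(−δ S_j),    S_j = Σ_{i ∈ I_Y} Y_ij,

normalised to w_j = w̃_j / Σ_k w̃_k, giving the MNAR estimate
θ̂(δ) = Σ_j w_j θ̂_j with weighted variance components
V_W = Σ_j w_j se_j² and V_B = Σ_j w_j (θ̂_j − θ̂(δ))², combined as
V_W + (1 + 1/m) V_B. The weights are the importance ratio between the
MNAR and MAR imputation distributions implied by the selection model when
α and γ are treated as known.

### Imputation draws

Continuous outcome (normal-linear model on an intercept and X, fitted to
the n₀ complete cases, q = 2 coefficients): per imputation,
σ*² = σ̂²(n₀−q)/χ²_{n₀−q} with σ̂² the unbiased residual-variance
estimate, then β* ~ N(β̂, σ*²(X₀ᵀX₀)⁻¹), then independent N(0, σ*²) noise
added to the linear predictor at each missing cell. The unbiased divisor
n₀−q keeps the χ² scaling coherent. Requires n₀ ≥ q + 2 so that the χ²
degrees of freedom are at least 2.

Binary outcome (logistic model): β* ~ N(MLE, I⁻¹) with I the observed
Fisher information at the MLE (the standard asymptotic posterior
approximation), then Bernoulli draws at expit(β*₀ + β*₁x). Separation or
non-convergence raises an error rather than silently falling back.

Draw order is fixed (variance, coefficients, outcome noise, per
imputation, in imputation order) so a seed fully determines the
imputation set. Observed values are never altered.

### Why the estimator fails, and what the package asserts about it

Because σ*² is drawn from a scaled inverse chi-square, the posterior
predictive of S_j is Student-t with n₀−q degrees of freedom: polynomial
tails. The weights are exponential in S_j, so the importance ratio is
unbounded and the weighted estimator is not consistent as m → ∞: with
enough imputations a single extreme draw takes essentially all the weight.
Two finite-m consequences are encoded as tests: the replicate distribution
of the MNAR estimate has heavier tails at m = 1000 than at m = 5, and the
maximum normalised weight stays of order one instead of decaying like the
uniform level 1/m (m · E[max weight] grows roughly two orders of magnitude
from m = 5 to m = 1000 in the canonical continuous scenario). The mean of
the maximum weight itself is *not* monotone in m at these scales — at
strong departures it is already ≈0.9 at m = 5 — which is why the
concentration is measured relative to 1/m.

## Diagnostics and δ-range selection

Two plots probe the support condition of the importance-sampling argument:
normalised weight against per-imputation estimate (reference line at 1/m,
pooled MAR estimate marked), and the running weighted estimate over the
first k imputations (vertical steps expose late dominant imputations; the
per-imputation estimates are rugged on the right axis).

The δ-range selection evaluates the normalised weights on a grid of
candidate δ (default −2…2, step 0.01) and keeps values where (i) the
maximum normalised weight is ≤ 0.5 and (ii) at least five weights are
≥ 1/m. "At or above 1/m" uses tolerance 1e-12 — read strictly, δ = 0
itself (all weights exactly 1/m) would fail. The reported interval is the
contiguous passing run containing 0 when 0 passes, else the widest run;
an empty passing set is a legitimate result, not an error. Both
thresholds are exposed as parameters. A selected range reflects only
weight behaviour under the MAR imputations — it is not an estimate of δ,
which is unidentifiable; the sign and plausible magnitude of δ must come
from subject-matter knowledge.

## Synthetic data and the evaluation scenarios

The generator emulates two population models: (X, Y) bivariate normal
(default means 0, variances 1, correlation 0.5, so the true regression
slope is ρ√(var_y/var_x) = 0.5) and a binary model with X ~ N(0, 1) and
logit P(Y=1) = Φ₀ + Φ₁X. The binary generating values are Φ₀ = 0 and
Φ₁ = 0.5: Φ₀ = 0 makes the true marginal proportion exactly 0.5 by
symmetry, and 0.5 is the canonical slope. Deletion is Bernoulli per
subject through the selection model — the achieved missingness fraction is
stochastic, not forced to 50% — with the canonical parameter sets
(α, γ, δ) = (0, 1, 1) and (0, 0.8, 0.5) for the continuous model and
(−0.4, 1, 1) and (−0.1, 1, 0.5) for the binary model, each giving ≈50%
missingness at n = 100. α values are taken as given rather than re-solved
for an exact 50% rate. Missingness predictability is summarised by the
rank-based (Mann-Whitney, tie-averaged) AUROC of a logistic model of R on
(X, Y) fitted to the pre-deletion data; it is fitted by IRLS so that
perfectly separable indicators yield AUROC 1 instead of an MLE failure.

What the generator does not emulate: covariate missingness, multivariate
outcomes, model misspecification (the imputation model is exactly the
generating regression), non-logistic selection, or clustered/longitudinal
structure. Passing tests therefore demonstrate the estimator's behaviour
under ideal conditions — bias that appears here is intrinsic to the
weighting method, not an artefact of model misfit — and say nothing about
additional problems real data would add.

Simulation studies derive replicate i's streams from
SeedSequence(master, spawn_key=(i,)) split into generation, deletion and
imputation children, so any replicate is regenerable in isolation and
results are independent of execution order. Within a replicate the
imputation set is drawn once at max(m_list) and smaller m use its leading
prefix, pairing the across-m comparisons. Replicates whose draws are
degenerate (too few observed outcomes, one-class or separated logistic
fits) are recorded as failed and excluded; a study errors out if more than
10% fail. Default problem sizes are 200 replicates with m ∈ {5, 10, 50}
(the "reduced mode" used by the test suite); the full published layout
(1000 replicates, m up to 1000) runs through the same code path via the
CLI's `--full` flag or a scenario config.

## Estimands and pooling conventions

Marginal mean (se = sd/√n with the n−1 divisor), marginal proportion
(binomial plug-in se, pooled on the probability scale), OLS slope
(conventional unbiased residual-variance se) and logistic MLE slope (Wald
se). Per-imputation estimates must have finite, strictly positive se.
Rubin pooling requires m ≥ 2. The weighted between-variance is used
verbatim — no m/(m−1) correction — so at δ = 0 the MNAR point estimate
equals the Rubin estimate exactly while the between-variance equals
(m−1)/m times Rubin's. Intervals use a normal reference; no
degrees-of-freedom rule is applied to the pooled variances.

## Numerical choices

Weights are computed in log space with max-subtraction before
exponentiation; raw weights are therefore reported up to a common positive
factor (they are only defined up to proportionality). A naive
direct-summation implementation is kept in the test suite as an oracle and
agrees to 1e-10 on small instances. Equal sums give exactly uniform
weights at any δ; normalised weights are invariant to adding a constant to
every imputed value. Grid endpoints of the δ-range are grid points, not
interpolated roots.

## Known limitations

- Single incomplete outcome and a single covariate; no chained equations,
  no missingness in X.
- The weights treat α and γ as known; integrating them over their
  posterior (the theoretically correct weighting) is out of scope.
- The weighted variance has no established df rule; normal-reference
  intervals undercover when the weights are degenerate — by design the
  diagnostics, not the interval, are the safeguard.
- The estimator itself is not recommended at large m: the package exists
  as much to demonstrate and diagnose that failure as to compute the
  estimate.
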