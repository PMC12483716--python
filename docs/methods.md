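# Methods

## The models

`eirmix` targets long-format person-by-item binary response data: one row per
(person *j*, item *i*) pair with a response `y_ji ∈ {0,1}` and predictors at
the person level, the item level, or the pair level.

**EIRM (explanatory item response model).** A logistic mixed model with
crossed random intercepts,

    logit P(y_ji = 1) = x_ji' β + θ_j + b_i,
    θ_j ~ N(0, σ²_person),  b_i ~ N(0, σ²_item),

where `x_ji` stacks an intercept, dummy-coded nominal predictors and
mean-centered continuous predictors. The two random factors are crossed:
every observation carries one person effect and one item effect. On the
latent-response scale the residual variance of a logistic model is π²/3, so a
random-intercept variance σ² implies a conditional intraclass correlation
σ²/(σ² + π²/3) among latent responses sharing that intercept (conditional on
the other factor). The design variance levels 0.7 and 2.8 correspond to
conditional ICCs of 0.175 and 0.460.

**RF.** A bagged ensemble of Gini-split classification trees with per-split
feature subsampling (`mtry`), grown to purity (minimum node size 1). Nominal
predictors enter as integer category codes and trees split on the ordered
codes; with at most three categories per nominal predictor this dialect is
equivalent in expectation to category-subset splits for a binary outcome.
Out-of-bag (OOB) class-1 probabilities are the average of per-tree class
proportions over the trees in which a row was out of bag. Tuning is a grid
search over (`mtry`, number of trees) by repeated stratified k-fold
cross-validation scored by accuracy at the 0.5 threshold, ties broken toward
the smaller `mtry` and fewer trees.

**EIRM-RF.** The hybrid replaces the linear fixed part of the EIRM by a slope
on forest-predicted probabilities:

    logit P(y_ji = 1) = γ0 + γ1 · p̂RF_ji + θ_j + b_i.

Estimation alternates between the two components:

1. fit the forest to the current labels and predict `p̂RF` for the training
   rows;
2. fit the crossed logistic mixed model of the *original* response on
   `(1, p̂RF)`;
3. compose the fitted probability `p̃ = expit(γ̂0 + γ̂1 p̂RF + θ̂_j + b̂_i)`;
4. build the next pseudo-response from `v = y + p̃`: keep `y` when `v < 0.5`
   or `v > 1.5` (response and fit agree), otherwise draw Bernoulli(`p̃`);
5. repeat from step 1 with the pseudo-response until the forest's OOB Brier
   score changes by less than `tol` (default 1e-4) between iterations, or a
   fixed iteration budget is exhausted.

`p̂RF` for training rows is the plain all-trees prediction on the training
frame (the convention of the reference estimation code, which predicts on the
data it was trained on); `prefer_oob=True` switches to the leakage-free OOB
aggregate. The two conventions trade off differently: in-bag predictions make
the hybrid dominate both components in-sample, OOB predictions give more
honest absolute accuracy numbers. Note that the OOB-Brier convergence rule
operates below the Monte-Carlo noise floor of refitting a forest to freshly
drawn pseudo-responses (≈2e-3 at 1000 rows / a few hundred trees), so in
practice the rule fires by chance; the study harnesses therefore run a fixed
iteration budget (6 iterations for the accuracy study, 4 for the
interpretation study). Fit quality is stable after about two iterations.

**Unexplained variability.** The share of latent-scale variance not captured
by the forest term is reported as
`(σ̂²_person + σ̂²_item + π²/3) / (Var(γ̂1 p̂RF) + σ̂²_person + σ̂²_item + π²/3)`
by default. This quantity has no single canonical form; two alternatives
(`random_only`, `icc_sum`) are selectable and the choice is recorded in the
output.

## Laplace estimation of the crossed GLMM

No Python library fits logistic mixed models with *crossed* random intercepts
by Laplace approximation, so the engine is implemented here.

- **Inner problem.** Given variances, a damped Newton search finds the joint
  mode of (β, θ, b) of the penalized Bernoulli log-likelihood. The Hessian
  has exploitable structure: the person block is diagonal, the item block is
  a small dense matrix, and the cross block is sparse; one Newton step costs
  O(n + I³ + p³) via block elimination (person block eliminated first).
- **Laplace objective.** log L ≈ ℓ_pen(mode) − ½ log det(H_uu) − ½ J log
  σ²_person − ½ I log σ²_item, with the log-determinant computed from the
  same block factorization.
- **Outer problem.** A Nelder-Mead search over (log σ²_person, log σ²_item)
  with β profiled inside the inner Newton, followed by a joint L-BFGS-B
  refinement over (β, log σ²) with the random-effect modes re-found per
  evaluation. The refinement matters because the log-determinant depends on β
  through the IRLS weights; after it, estimates agree with a tightly
  converged reference mixed-model implementation to ~1e-6 relative on a
  320-row fixture (frozen in the test suite). `refine_beta=False` skips the
  second stage; the study harnesses use it for speed, since orderings and
  recovery are unaffected at their scales.
- **Edge cases.** Variances at the boundary (σ̂² < 1e-8) are flagged, the
  corresponding random term dropped, and the fit re-profiled; with both
  variances fixed at zero the procedure reduces exactly to iteratively
  reweighted least squares for logistic regression. A constant response
  raises a separation error. Under (quasi-)complete separation — which the
  hybrid can induce when a memorizing forest feeds near-perfect probabilities
  into the slope — the fitter either raises (default) or returns the stalled
  estimates flagged non-converged (`on_divergence="flag"`, used inside
  EIRM-RF). Inner tolerance 1e-8 on the gradient norm, outer 1e-6 on the
  log-likelihood; starting values: β from plain logistic regression behavior
  (zero start with damping), σ² = 0.5.
- Wald covariance for β comes from the Schur complement of the joint Hessian
  at the optimum. Predictions for unseen persons/items use a random effect of
  0 (population-average on the logit scale).

## Interpretation suite

All four tools operate on an arbitrary `predict(X) -> probability` function.

- **Importance**: impurity-decrease (Gini) importances from the forest,
  optionally normalized to a top score of 100.
- **Partial dependence**: the average prediction with one feature forced
  across a grid of observed values (equispaced once more than `grid_size`
  distinct values exist; capped at 50 by default).
- **Accumulated local effects**: quantile bins; within each bin the average
  prediction difference between the bin edges over the rows in the bin;
  cumulative sum reported at the edges and centered so the occupancy-weighted
  mean (counts split evenly between adjacent edges, i.e. trapezoidal
  occupancy) is zero. Restricted to continuous features.
- **H-statistic**: Friedman–Popescu variance fractions. Overall, for feature
  j: the fraction of centered prediction variance not explained by
  PD_j + PD_{−j}; pairwise: the fraction of the two-way PD surface's variance
  not explained by PD_j + PD_k. The reported value is H² in [0,1] (clipped at
  0 for round-off); the square root is available. Because the partial
  dependence decomposition is quadratic in rows, H is evaluated on a seeded
  subsample (default 200 rows), recorded in the result.

## Synthetic data generators

**Predictors.** 13 person-level predictors (9 standard normal, 4 nominal with
2–3 categories) and 3 nominal item-level predictors, drawn through a latent
Gaussian copula with a jittered exchangeable correlation matrix, nominal
columns thresholded at equal-probability cutpoints. An accept–reject loop
(with adaptive rescaling of the latent correlation, fresh seed substream per
attempt) drives the *median* of the pairwise Pearson correlations among the
16 encoded predictors in the long-format crossing to the target level (0.003
or 0.400, tolerance ±0.05). Cross-level (person × item) pairs are
structurally near zero in a crossed design, so the latent within-table
correlation adapts upward to compensate. The interquartile range of the
pairwise correlations is reported but not enforced: at a fixed target it is
dominated by sampling noise and therefore scales as ~1.35/√J (≈0.07 at
J≈360, ≈0.13 at J=100), so it is not a free parameter of the generator.

**Linear truth.** The `simple` structure is intercept 0 plus main effects of
every predictor (dummy-coded nominals), coefficients i.i.d. Uniform(−1, 1)
drawn once and held fixed across replications. The `complex` structure adds a
person-by-item interaction block — each continuous person predictor × the
first dummy of the first item predictor, and each person-level dummy × the
first dummy of the second item predictor — with Uniform(−1, 1) coefficients.
The realized mean/variance of the linear predictor depends on the coefficient
draw; typical draws give variances of roughly 2–5 on the logit scale.
Responses are Bernoulli(expit(η + θ_j + b_i)) with random effects drawn fresh
per replication.

**Tree truth.** A single explicit binary tree over 2 randomly selected
item-level and 5 randomly selected person-level predictors, depth 3–5,
continuous thresholds uniform over the central 80% of observed values,
nominal splits on random proper category subsets, leaf probabilities
Uniform(0.05, 0.95). Every selected feature is forced to appear at least once
(internal nodes consume a shuffled queue of the selected features before
choosing freely), since a truth in which selected features have exactly zero
effect makes "recovery of the selected structure" untestable. Outcomes follow
`logit p = γ0 + γ1 · p_tree(x) + θ_j + b_i` with defaults γ0 = −2, γ1 = 4
(tree probabilities 0→1 span logits −2→2).

**Ground-truth interpretation values.** By default the truth is the
interpretation of a forest *distilled* onto the tree's exact probabilities
(every row duplicated with labels 1/0 weighted by p/1−p — a noise-free fit).
This puts truth and estimate on the same footing: both carry the forest
dialect's biases (smoothing, split-eligibility effects, item-identity
absorption), so agreement scores isolate the effect of noise and random
effects rather than the tree-vs-forest representation gap. `mode="tree"`
interprets the bare tree instead, in which case unselected features score
exactly zero.

## Study harnesses

Both harnesses derive every per-condition and per-replication seed from one
master seed through counter-indexed `SeedSequence` substreams; results are
bit-for-bit reproducible and independent of execution order. Replications
that fail (e.g. a collinear design in a tiny item sample) are logged and
skipped, and a condition is flagged invalid when more than 5% fail.

**Accuracy study.** Per condition, predictors and coefficients are drawn
once; per replication, new random effects and responses. EIRM, RF and EIRM-RF
are fit to the same datasets and scored in-sample by AUC and Brier score.
EIRM and EIRM-RF use fitted probabilities including random effects (the
explanatory-use convention); RF is scored both on OOB probabilities (the
headline number) and in-sample. Desk-scale defaults: 20 replications,
100×10, 200 trees, mtry 4, 6 hybrid iterations. Collinear dummy columns are
dropped (pivoted QR) before the EIRM fit.

**Interpretation-recovery study.** Per condition, one predictor draw and one
true tree define ground truth; per replication, outcomes are regenerated and
both EIRM-RF and a plain RF are fit, their forests interpreted, and Spearman
agreement with truth scored per method: importance and overall-H as rank
correlations across all 16 predictors; PD/ALE as per-predictor curve
correlations on a shared grid averaged over the tree's selected predictors
(continuous only for ALE; undefined correlations from flat curves are
skipped, not coerced to zero). Preprocessing skips mean-centering here so the
empirical grids coincide with the truth's. Desk-scale defaults: 8
replications per condition, 300 trees, H-subsample 80 rows, PD evaluated on a
300-row subsample, 12-point grids, 6 ALE bins, 4 hybrid iterations.
Agreement scores at this scale retain visible Monte-Carlo noise, and — more
fundamentally — their level is a property of the particular regenerated true
tree: across trees the same condition can yield overall-H agreement anywhere
from ~0.55 to ~0.9. Point comparisons against any fixed reference values
should therefore be read per-tree, not as universal constants.

**Empirical-style pipeline.** `analyze_empirical` chains: load/validate →
near-zero-variance screen (frequency ratio > 19 and unique fraction < 10%)
and mean-centering → intercept-only crossed model for the two conditional
ICCs → linear-effects EIRM coefficient table → (optionally CV-tuned) forest →
EIRM-RF → accuracy table for all models → full interpretation suite on the
hybrid's forest. It bundles no data; any long-format CSV plus a YAML/JSON
predictor schema can be supplied through the `eirmix empirical` subcommand.

## What the synthetic conditions do and do not show

The generators emulate the crossed design, the predictor counts and types,
the correlation levels, the variance levels and the sample sizes of the study
designs, with noise that is exactly Bernoulli given the latent structure.
They do not emulate real response processes: no missingness (listwise
deletion is exercised only on constructed fixtures), no measurement drift, no
dependence between predictors and random effects (the model's own
assumption), and item samples of 10–30 make item-level effect estimates
intrinsically unstable in ways a 14-item empirical study shares only partly.
Passing tests show the machinery is correct and the qualitative orderings
hold under the stated conditions — not that effect sizes transfer to any
particular dataset.

## Known limitations

- Random slopes on the forest term, recalibration of `p̂RF` (logit transform,
  Platt/isotonic), and nested or longitudinal random-effect structures are
  out of scope.
- The in-sample accuracy comparison favors models with more effective
  parameters; no data-splitting machinery is provided.
- The alternation has no convergence theory; the OOB-Brier stopping rule is
  stochastic (see above) and the iteration budget is the practical control.
- Gini importances inherit the known biases of impurity measures (toward
  features with many split points, and toward features that proxy cluster
  identity when random effects are present). The distilled-truth convention
  in the recovery study shares, rather than removes, these biases.
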