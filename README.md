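# eirmix

Explanatory modelling of person-by-item binary responses with random forests
inside a crossed random-effects item response model.

## The problem

Item response data are cross-classified: every response belongs to one person
*and* one item, and responses sharing a person (or an item) are correlated.
The explanatory item response model (EIRM) handles this with a logistic mixed
model,

    logit P(y_ji = 1) = x_ji' β + θ_j + b_i,
    θ_j ~ N(0, σ²_person),  b_i ~ N(0, σ²_item),

but assumes linear, additive predictor effects. Random forests capture
nonlinearities and interactions among person- and item-level predictors
automatically, but ignore the crossed correlation structure. `eirmix`
implements the hybrid **EIRM-RF**, which replaces the linear fixed part with
a slope on forest-predicted probabilities,

    logit P(y_ji = 1) = γ0 + γ1 · p̂RF_ji + θ_j + b_i,

estimated by alternating forest fits and crossed-random-intercept logistic
mixed-model fits (by Laplace approximation) on a pseudo-response built from
the current fitted probabilities, until the forest's out-of-bag Brier score
stabilizes. The forest component is then probed with interpretable-ML tools:
Gini importances, partial dependence, accumulated local effects (ALE), and
the Friedman–Popescu H-statistic of interaction strength.

The package is aimed at psychometricians and applied statisticians who want
to *explain* variability in item responses from person and item predictors —
it also fits the plain EIRM and plain forests for comparison, computes
conditional intraclass correlations σ²/(σ² + π²/3) on the latent logistic
scale, and ships seeded synthetic-data generators and study harnesses for
method evaluation.

## Worked example

```python
import numpy as np
from eirmix import (SimulationSpec, gen_predictors, linear_predictor,
                    gen_eirm_dataset, preprocess, encode, fit_crossed_logit,
                    fit_eirm_rf, ForestParams, auc, predict_prob)

# simulate 100 persons x 10 items with crossed random effects (variance 0.7,
# i.e. conditional ICC 0.175) and a simple linear truth
spec = SimulationSpec(n_persons=100, n_items=10, sigma2_person=0.7,
                      sigma2_item=0.7)
persons, items, schema, _ = gen_predictors(spec, seed=11)
eta, _ = linear_predictor(persons, items, schema, "simple", seed=12)
table = gen_eirm_dataset(persons, items, schema, eta, 0.7, 0.7, seed=13)

prep = preprocess(table)               # centering + near-zero-variance screen
y = prep.table.y
pc, _ = prep.table.person_codes()
ic, _ = prep.table.item_codes()

# baseline EIRM (linear effects)
X, names = encode(prep, "eirm")
eirm = fit_crossed_logit(y, X, pc, ic, beta_names=names)
print(f"EIRM    sigma2=({eirm.sigma2_person:.3f}, {eirm.sigma2_item:.3f}) "
      f"AUC={auc(y, predict_prob(eirm, X, pc, ic)):.3f}")

# hybrid EIRM-RF
fit = fit_eirm_rf(prep, ForestParams(mtry=4, n_trees=200), max_iter=6, seed=1)
print(f"EIRM-RF gamma1={fit.gamma1:.2f} "
      f"sigma2=({fit.glmm.sigma2_person:.3f}, {fit.glmm.sigma2_item:.3f}) "
      f"AUC={auc(y, fit.fitted_prob):.3f}")
```

prints

```
EIRM    sigma2=(0.177, 0.170) AUC=0.918
EIRM-RF gamma1=7.94 sigma2=(0.000, 0.590) AUC=0.959
```

Reading the output: the EIRM estimates modest random-intercept variances for
this particular replication (variance estimates at 100 persons and 10 items
are noisy) and reaches an in-sample AUC of 0.918 with correctly specified
linear effects. The hybrid's slope on the forest probabilities is strongly
positive (γ̂1 ≈ 7.9) and its fitted probabilities discriminate better
(AUC 0.959). Its person variance collapses to the boundary at 0 — the
person-level features identify persons almost uniquely, so the forest term
already absorbs person-level variation; the item variance, supported by only
three coarse item predictors, survives. `fit.summary()` adds the iteration
trace of the out-of-bag Brier score and the unexplained-variability share;
`eirmix.interpret` provides importances, PD/ALE curves and H-statistics for
the forest component.

A command-line interface mirrors the library:
`eirmix simulate|prep|fit-eirm|fit-rf|fit-eirmrf|evaluate|study1|study2|empirical`
(see `eirmix --help`).

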