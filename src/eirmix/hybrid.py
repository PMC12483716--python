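"""The EIRM-RF hybrid: a random forest for the fixed part of a crossed
random-intercept logistic model, estimated by alternating forest and
mixed-model fits.

The model is

    logit P(y_ji = 1) = gamma0 + gamma1 * pRF_ji + theta_j + b_i,

where ``pRF_ji`` is the forest-predicted probability from person- and
item-level features.  Estimation alternates: fit the forest, regress the
response on the forest predictions with crossed random intercepts (Laplace
GLMM), compose the fitted probability, then rebuild a pseudo-response by the
split function below and refit, until the forest's out-of-bag Brier score
stabilizes.

Forest predictions for the training rows are the plain all-trees predictions
on the training frame (the reference estimation code predicts on the data it
was trained on); ``prefer_oob=True`` switches to the leakage-free out-of-bag
aggregate instead.  The forest's own OOB Brier score is always the
convergence metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_prep import PreparedData, encode
from .errors import ParameterError
from .forest import ForestFit, ForestParams, fit_forest
from .glmm import LOGISTIC_VARIANCE, GlmmFit, fit_crossed_logit, predict_prob

UNEXPLAINED_DEFINITIONS = ("total_ratio", "random_only", "icc_sum")


@dataclass
class EirmRfFit:
    forest: ForestFit
    glmm: GlmmFit
    fitted_prob: np.ndarray
    p_rf: np.ndarray
    trace: list
    n_iter: int
    converged: bool
    seeds: dict
    person_ids: list
    item_ids: list
    prepared: PreparedData = None
    target_history: list = field(default_factory=list)

    @property
    def gamma0(self) -> float:
        return float(self.glmm.beta[0])

    @property
    def gamma1(self) -> float:
        return float(self.glmm.beta[1])

    def summary(self) -> dict:
        return {
            "gamma0": self.gamma0,
            "gamma1": self.gamma1,
            "glmm": self.glmm.summary(),
            "oob_error_trace": [float(t) for t in self.trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "unexplained_variability": unexplained_variability(self),
        }


def make_target_outcome(y, p, rng) -> np.ndarray:
    """Dichotomize ``v = y + p`` into the next iteration's pseudo-response.

    ``v < 0.5`` maps to 0 and ``v > 1.5`` maps to 1 (the response and the
    fitted probability agree, so the original response is kept); in between,
    the outcome is a Bernoulli(p) draw.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    v = y + p
    out = np.where(v < 0.5, 0, np.where(v > 1.5, 1, -1))
    mid = out == -1
    if mid.any():
        draws = (rng.random(mid.sum()) < p[mid]).astype(int)
        out[mid] = draws
    return out.astype(int)


def fit_eirm_rf(
    prepared: PreparedData,
    rf_params: ForestParams,
    tol: float = 1e-4,
    max_iter: int = 50,
    seed: int = 0,
    prefer_oob: bool = False,
    glmm_kwargs: dict | None = None,
) -> EirmRfFit:
    """Fit EIRM-RF on prepared long-format data.

    ``tol`` is the absolute change in the forest's OOB Brier score below which
    the alternation is declared converged; ``seed`` drives both the per-
    iteration forest seeds and the Bernoulli draws of the split function via
    iteration-indexed substreams.
    """
    table = prepared.table
    y = table.y
    if len(np.unique(y)) < 2:
        raise ParameterError("response is single-class")
    features, feat_names = encode(prepared, mode="forest")
    pcodes, person_ids = table.person_codes()
    icodes, item_ids = table.item_codes()
    glmm_kwargs = dict(glmm_kwargs or {})
    glmm_kwargs.setdefault("on_divergence", "flag")

    ss = np.random.SeedSequence(seed)
    forest_seeds = ss.spawn(max_iter + 1)
    bern_ss = ss.spawn(1)[0].spawn(max_iter)

    def forest_seed(t):
        return int(forest_seeds[t].generate_state(1)[0] % (2**31 - 1))

    def fit_step(labels, t):
        params = ForestParams(
            mtry=rf_params.mtry, n_trees=rf_params.n_trees,
            min_node_size=rf_params.min_node_size, seed=forest_seed(t),
        )
        forest = fit_forest(features, labels, params, allow_degenerate=True,
                            feature_names=feat_names)
        p_rf = forest.train_prob(prefer_oob=prefer_oob)
        if np.std(p_rf) < 1e-12:
            # constant forest output: slope is unidentified, fit intercept only
            X = np.ones((len(y), 1))
            g = fit_crossed_logit(y, X, pcodes, icodes,
                                  beta_names=["gamma0"], **glmm_kwargs)
            beta = np.array([g.beta[0], 0.0])
            cov = np.zeros((2, 2))
            cov[0, 0] = g.beta_cov[0, 0]
            glmm = GlmmFit(
                beta=beta, beta_cov=cov, se=np.sqrt(np.diag(cov)),
                sigma2_person=g.sigma2_person, sigma2_item=g.sigma2_item,
                person_modes=g.person_modes, item_modes=g.item_modes,
                laplace_loglik=g.laplace_loglik, converged=g.converged,
                boundary=g.boundary, n_inner_iters=g.n_inner_iters,
                n_outer_iters=g.n_outer_iters,
                beta_names=["gamma0", "gamma1"],
            )
        else:
            X = np.column_stack([np.ones(len(y)), p_rf])
            glmm = fit_crossed_logit(y, X, pcodes, icodes,
                                     beta_names=["gamma0", "gamma1"],
                                     **glmm_kwargs)
        eta = glmm.beta[0] + glmm.beta[1] * p_rf
        eta = eta + glmm.person_modes[pcodes] + glmm.item_modes[icodes]
        p_tilde = 0.5 * (1.0 + np.tanh(0.5 * eta))
        return forest, p_rf, glmm, p_tilde

    forest, p_rf, glmm, p_tilde = fit_step(y, 0)
    trace = [forest.oob_error]
    converged = False
    n_iter = 1
    for t in range(1, max_iter):
        rng = np.random.default_rng(bern_ss[t - 1])
        y_t = make_target_outcome(y, p_tilde, rng)
        forest, p_rf, glmm, p_tilde = fit_step(y_t, t)
        trace.append(forest.oob_error)
        n_iter = t + 1
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return EirmRfFit(
        forest=forest, glmm=glmm, fitted_prob=p_tilde, p_rf=p_rf,
        trace=trace, n_iter=n_iter, converged=converged,
        seeds={"master": seed}, person_ids=person_ids, item_ids=item_ids,
        prepared=prepared,
    )


def predict_eirm_rf(fit: EirmRfFit, rows, include_random: bool = True) -> np.ndarray:
    """Predict probabilities for new long-format rows.

    Rows are encoded under the training schema; the forest probability enters
    the linear predictor with slope gamma1, and random intercepts are added
    for persons/items seen in training (unseen clusters contribute 0).
    """
    features, _ = encode(fit.prepared, mode="forest", df=rows)
    p_rf = fit.forest.predict_prob(features)
    X = np.column_stack([np.ones(len(p_rf)), p_rf])
    pidx = np.array([fit.person_ids.index(v) if v in fit.person_ids else -1
                     for v in rows["person_id"]]) if include_random else None
    iidx = np.array([fit.item_ids.index(v) if v in fit.item_ids else -1
                     for v in rows["item_id"]]) if include_random else None
    return predict_prob(fit.glmm, X, pidx, iidx, include_random=include_random)


def unexplained_variability(fit: EirmRfFit, definition: str = "total_ratio") -> float:
    """Share of latent-scale variance left unexplained by the forest term.

    ``total_ratio`` (default): (s2_person + s2_item + pi^2/3) divided by
    (Var(gamma1 * pRF) + s2_person + s2_item + pi^2/3).  ``random_only``
    drops the explained term from the denominator's complement and returns
    (s2_person + s2_item) / (s2_person + s2_item + pi^2/3); ``icc_sum`` is the
    sum of the two conditional ICCs.  The chosen definition is a documented
    modelling convention — the quantity has no single canonical form.
    """
    if definition not in UNEXPLAINED_DEFINITIONS:
        raise ParameterError(
            f"unknown definition {definition!r}; choose from {UNEXPLAINED_DEFINITIONS}")
    s2 = fit.glmm.sigma2_person + fit.glmm.sigma2_item
    if definition == "random_only":
        return s2 / (s2 + LOGISTIC_VARIANCE)
    if definition == "icc_sum":
        return (fit.glmm.sigma2_person / (fit.glmm.sigma2_person + LOGISTIC_VARIANCE)
                + fit.glmm.sigma2_item / (fit.glmm.sigma2_item + LOGISTIC_VARIANCE))
    explained = float(np.var(fit.gamma1 * fit.p_rf))
    return (s2 + LOGISTIC_VARIANCE) / (explained + s2 + LOGISTIC_VARIANCE)
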