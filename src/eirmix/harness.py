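"""Replication harnesses: the two simulation studies and the empirical-style
analysis pipeline.

Study 1 compares the in-sample accuracy (AUC, Brier) of the linear-effects
mixed model (EIRM), a plain random forest, and the hybrid (EIRM-RF) on data
generated from the crossed-random-intercept logistic model under varying
fixed-effect structure, random-effect variance and sample size.  Study 2
generates outcomes from an explicit true tree and scores, per interpretation
method, the Spearman agreement between the interpretation of a fitted forest
(the RF inside EIRM-RF, and a plain RF) and the interpretation of the true
tree itself.

All randomness flows from one master seed through counter-indexed
``SeedSequence`` substreams, so results are reproducible bit-for-bit and do
not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .data_prep import (ResponseTable, drop_collinear, encode,
                        load_long_table, preprocess)
from .errors import EirmixError
from .evaluate import auc, brier
from .forest import ForestParams, fit_forest, tune_forest
from .glmm import fit_crossed_logit, predict_prob
from .hybrid import fit_eirm_rf
from .interpret import (accumulated_local_effects, gini_importance_table,
                        h_statistic, partial_dependence, spearman_agreement)
from .simulate import (SimulationSpec, encode_features, gen_eirm_dataset,
                       gen_eirmtree_dataset, gen_predictors, gen_true_tree,
                       linear_predictor, true_interpretation_values)

log = logging.getLogger("eirmix")


@dataclass(frozen=True)
class Study1Condition:
    structure: str = "simple"
    sigma2: float = 0.7
    n_persons: int = 100
    n_items: int = 10

    def label(self) -> str:
        return f"{self.structure}/s2={self.sigma2}/{self.n_persons}x{self.n_items}"


@dataclass(frozen=True)
class Study2Condition:
    target_corr: float = 0.003
    sigma2: float = 0.7
    n_persons: int = 100
    n_items: int = 10

    def label(self) -> str:
        return (f"corr={self.target_corr}/s2={self.sigma2}/"
                f"{self.n_persons}x{self.n_items}")


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _fit_three_models(table: ResponseTable, rf_params: ForestParams,
                      eirm_rf_iters: int, seed: int, center: bool = True):
    """Fit EIRM, RF and EIRM-RF to one dataset; return accuracy rows."""
    prep = preprocess(table, center=center)
    y = prep.table.y
    pc, _ = prep.table.person_codes()
    ic, _ = prep.table.item_codes()

    X, names = encode(prep, "eirm")
    X, names, _ = drop_collinear(X, names)
    g = fit_crossed_logit(y, X, pc, ic, refine_beta=False, beta_names=names)
    p_eirm = predict_prob(g, X, pc, ic, include_random=True)

    F, fnames = encode(prep, "forest")
    ff = fit_forest(F, y, replace(rf_params, seed=seed),
                    feature_names=fnames)
    p_rf_oob = ff.train_prob(prefer_oob=True)
    p_rf_in = ff.inbag_prob

    hf = fit_eirm_rf(prep, rf_params, max_iter=eirm_rf_iters, seed=seed,
                     glmm_kwargs={"refine_beta": False})

    return {
        "eirm": (auc(y, p_eirm), brier(y, p_eirm)),
        "rf_oob": (auc(y, p_rf_oob), brier(y, p_rf_oob)),
        "rf_insample": (auc(y, p_rf_in), brier(y, p_rf_in)),
        "eirm_rf": (auc(y, hf.fitted_prob), brier(y, hf.fitted_prob)),
    }


def run_study1(
    conditions,
    reps: int = 20,
    seed: int = 0,
    rf_params: ForestParams = ForestParams(mtry=4, n_trees=200),
    eirm_rf_iters: int = 6,
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Accuracy comparison of EIRM, RF and EIRM-RF over replications.

    Per condition: predictors and fixed-effect coefficients are drawn once
    and held fixed; random effects and responses are regenerated each
    replication, and all models are fit to the same datasets.  Returns one
    row per (condition, model) with mean AUC/Brier over completed
    replications, plus replication bookkeeping.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = np.random.SeedSequence(seed)
    cond_streams = master.spawn(len(list(conditions)))
    records = []
    for cond, cstream in zip(conditions, cond_streams):
        gen_ss, coef_ss, *rep_ss = cstream.spawn(2 + reps)
        spec = SimulationSpec(
            n_persons=cond.n_persons, n_items=cond.n_items,
            structure=cond.structure, sigma2_person=cond.sigma2,
            sigma2_item=cond.sigma2,
        )
        pdf, idf, schema, gen_info = gen_predictors(spec, _seed_int(gen_ss))
        eta, coefs = linear_predictor(pdf, idf, schema, cond.structure,
                                      _seed_int(coef_ss))
        per_model = {}
        failures = 0
        for r in range(reps):
            data_seed = _seed_int(rep_ss[r])
            try:
                table = gen_eirm_dataset(pdf, idf, schema, eta, cond.sigma2,
                                         cond.sigma2, data_seed)
                scores = _fit_three_models(table, rf_params, eirm_rf_iters,
                                           data_seed)
            except EirmixError as exc:
                failures += 1
                log.warning("study1 %s rep %d failed: %s", cond.label(), r, exc)
                continue
            for model, (a, b) in scores.items():
                per_model.setdefault(model, []).append((a, b))
        valid = failures / reps <= max_failure_rate
        for model, vals in per_model.items():
            arr = np.asarray(vals)
            records.append({
                "condition": cond.label(), "structure": cond.structure,
                "sigma2": cond.sigma2, "n_persons": cond.n_persons,
                "n_items": cond.n_items, "model": model,
                "mean_auc": float(arr[:, 0].mean()),
                "mean_brier": float(arr[:, 1].mean()),
                "n_reps": len(vals), "n_failures": failures, "valid": valid,
                "achieved_corr_median": gen_info["achieved_median"],
            })
    return pd.DataFrame.from_records(records)


def _curve_agreements(truth, forest, feats, selected, continuous, ale_bins,
                      h_sample, h_seed, pd_sample=None):
    """Spearman agreement of one fitted forest's interpretation with truth."""
    predict = forest.predict_prob
    order = list(feats.columns)
    if pd_sample is not None and pd_sample < len(feats):
        rng = np.random.default_rng(h_seed)
        pd_data = feats.iloc[rng.choice(len(feats), pd_sample, replace=False)]
        pd_data = pd_data.reset_index(drop=True)
    else:
        pd_data = feats

    imp_emp = pd.Series(forest.gini_importance, index=forest.feature_names)
    agree = {"importance": spearman_agreement(
        truth["importance"][order].to_numpy(), imp_emp[order].to_numpy())}

    pd_scores = []
    for name in selected:
        tc = truth["pd"][name]
        ec = partial_dependence(predict, pd_data, name, grid=tc.grid)
        rho = spearman_agreement(tc.values, ec.values)
        if np.isfinite(rho):
            pd_scores.append(rho)
    agree["pd"] = float(np.mean(pd_scores)) if pd_scores else float("nan")

    ale_scores = []
    for name in selected:
        if name not in continuous:
            continue
        tc = truth["ale"][name]
        ec = accumulated_local_effects(predict, feats, name, n_bins=ale_bins)
        rho = spearman_agreement(tc.values, ec.values)
        if np.isfinite(rho):
            ale_scores.append(rho)
    agree["ale"] = float(np.mean(ale_scores)) if ale_scores else float("nan")

    h_emp = [h_statistic(predict, feats, name,
                         n_sample=min(h_sample, len(feats)), seed=h_seed).value
             for name in order]
    agree["h"] = spearman_agreement(
        np.array([truth["h"][name] for name in order]), np.array(h_emp))
    return agree


def run_study2(
    conditions,
    reps: int = 20,
    seed: int = 0,
    rf_params: ForestParams = ForestParams(mtry=4, n_trees=150),
    eirm_rf_iters: int = 5,
    grid_size: int = 12,
    ale_bins: int = 6,
    h_sample: int = 50,
    pd_sample: int = 300,
    truth_mode: str = "rf",
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Recovery of tree-truth interpretation by EIRM-RF and plain RF.

    Per condition: one predictor draw and one true tree define the ground
    truth (importance, PD, ALE, overall H per predictor); each replication
    regenerates outcomes, fits EIRM-RF and a plain RF, and scores Spearman
    agreement per interpretation method.  Importance and H agreement are rank
    correlations across all predictors; PD/ALE agreement correlates the true
    and empirical curves on a shared grid and averages over the tree's
    selected predictors (continuous ones only for ALE).
    """
    master = np.random.SeedSequence(seed)
    cond_streams = master.spawn(len(list(conditions)))
    records = []
    for cond, cstream in zip(conditions, cond_streams):
        gen_ss, tree_ss, *rep_ss = cstream.spawn(2 + reps)
        spec = SimulationSpec(
            n_persons=cond.n_persons, n_items=cond.n_items,
            sigma2_person=cond.sigma2, sigma2_item=cond.sigma2,
            target_median_corr=cond.target_corr,
        )
        pdf, idf, schema, gen_info = gen_predictors(spec, _seed_int(gen_ss))
        tree = gen_true_tree(pdf, idf, schema, _seed_int(tree_ss))
        h_seed = _seed_int(tree_ss)
        truth = true_interpretation_values(
            tree, pdf, idf, schema, mode=truth_mode, grid_size=grid_size,
            ale_bins=ale_bins, h_sample=h_sample, mtry=rf_params.mtry,
            n_trees=rf_params.n_trees, seed=h_seed)
        feats = encode_features(pdf, idf, schema)
        continuous = {p.name for p in schema if p.kind == "continuous"}

        per_model = {"eirm_rf": [], "rf": []}
        failures = 0
        for r in range(reps):
            rseed = _seed_int(rep_ss[r])
            try:
                table = gen_eirmtree_dataset(tree, pdf, idf, schema,
                                             cond.sigma2, cond.sigma2, rseed)
                prep = preprocess(table, center=False)
                hf = fit_eirm_rf(prep, rf_params, max_iter=eirm_rf_iters,
                                 seed=rseed,
                                 glmm_kwargs={"refine_beta": False})
                F, fnames = encode(prep, "forest")
                rf = fit_forest(F, prep.table.y, replace(rf_params, seed=rseed),
                                feature_names=fnames)
            except EirmixError as exc:
                failures += 1
                log.warning("study2 %s rep %d failed: %s", cond.label(), r, exc)
                continue
            per_model["eirm_rf"].append(_curve_agreements(
                truth, hf.forest, feats, tree.selected, continuous,
                ale_bins, h_sample, h_seed, pd_sample=pd_sample))
            per_model["rf"].append(_curve_agreements(
                truth, rf, feats, tree.selected, continuous,
                ale_bins, h_sample, h_seed, pd_sample=pd_sample))
        valid = failures / reps <= max_failure_rate
        for model, rows in per_model.items():
            frame = pd.DataFrame(rows)
            rec = {
                "condition": cond.label(), "target_corr": cond.target_corr,
                "sigma2": cond.sigma2, "n_persons": cond.n_persons,
                "n_items": cond.n_items, "model": model,
                "n_reps": len(rows), "n_failures": failures, "valid": valid,
                "achieved_corr_median": gen_info["achieved_median"],
                "tree_depth": tree.depth,
            }
            for method in ("importance", "pd", "ale", "h"):
                rec[f"agree_{method}"] = float(frame[method].mean(skipna=True))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def analyze_empirical(
    data,
    schema,
    rf_params: ForestParams | None = None,
    tune: bool = False,
    mtry_grid=(2, 3, 4, 5),
    ntree_grid=(1000, 1500, 2000, 2500, 3000),
    cv_k: int = 10,
    cv_repeats: int = 5,
    eirm_rf_iters: int = 10,
    pd_grid_size: int = 50,
    ale_bins: int = 10,
    h_sample: int = 100,
    seed: int = 0,
) -> dict:
    """End-to-end explanatory analysis of one long-format dataset.

    Steps: load + preprocess; intercept-only crossed model for the two
    conditional ICCs; linear-effects EIRM coefficient table; (optionally
    tuned) random forest; EIRM-RF; accuracy comparison; interpretation suite
    on the EIRM-RF forest (importances, PD for every predictor, ALE for
    continuous predictors, overall H per predictor and pairwise H against the
    most interacting predictor).
    """
    table = data if isinstance(data, ResponseTable) else load_long_table(data, schema)
    prep = preprocess(table)
    y = prep.table.y
    pc, _ = prep.table.person_codes()
    ic, _ = prep.table.item_codes()

    null_fit = fit_crossed_logit(y, np.ones((len(y), 1)), pc, ic,
                                 beta_names=["(intercept)"])
    X, names = encode(prep, "eirm")
    X, names, dropped_cols = drop_collinear(X, names)
    eirm = fit_crossed_logit(y, X, pc, ic, beta_names=names)
    p_eirm = predict_prob(eirm, X, pc, ic, include_random=True)

    F, fnames = encode(prep, "forest")
    if rf_params is None:
        rf_params = ForestParams(mtry=min(4, F.shape[1]), n_trees=1000, seed=seed)
    tuning_table = None
    if tune:
        rf_params, tuning_table = tune_forest(
            F, y, mtry_grid=mtry_grid, ntree_grid=ntree_grid,
            k=cv_k, repeats=cv_repeats, seed=seed)
    rf = fit_forest(F, y, replace(rf_params, seed=seed), feature_names=fnames)
    p_rf_oob = rf.train_prob(prefer_oob=True)

    hf = fit_eirm_rf(prep, rf_params, max_iter=eirm_rf_iters, seed=seed)

    accuracy = [
        {"model": "eirm", "auc": auc(y, p_eirm), "brier": brier(y, p_eirm)},
        {"model": "rf_oob", "auc": auc(y, p_rf_oob), "brier": brier(y, p_rf_oob)},
        {"model": "rf_insample", "auc": auc(y, rf.inbag_prob),
         "brier": brier(y, rf.inbag_prob)},
        {"model": "eirm_rf", "auc": auc(y, hf.fitted_prob),
         "brier": brier(y, hf.fitted_prob)},
    ]

    feats = pd.DataFrame(F, columns=fnames)
    predict = hf.forest.predict_prob
    importance = gini_importance_table(hf.forest, normalize=True)
    pd_curves = {n: partial_dependence(predict, feats, n,
                                       grid_size=pd_grid_size)
                 for n in fnames}
    cont = [p.name for p in prep.schema if p.kind == "continuous"]
    ale_curves = {n: accumulated_local_effects(predict, feats, n,
                                               n_bins=ale_bins)
                  for n in cont}
    h_overall = {n: h_statistic(predict, feats, n,
                                n_sample=min(h_sample, len(feats)),
                                seed=seed).value
                 for n in fnames}
    top = max(h_overall, key=h_overall.get)
    h_pairwise = {f"{top}:{n}": h_statistic(predict, feats, (top, n),
                                            n_sample=min(h_sample, len(feats)),
                                            seed=seed).value
                  for n in fnames if n != top}

    return {
        "preprocess": prep.report(),
        "dropped_collinear": dropped_cols,
        "null_model": {
            "sigma2_person": null_fit.sigma2_person,
            "sigma2_item": null_fit.sigma2_item,
            "icc_person": null_fit.icc_person,
            "icc_item": null_fit.icc_item,
        },
        "eirm": eirm.summary(),
        "rf_params": asdict(rf_params),
        "tuning_table": tuning_table,
        "eirm_rf": hf.summary(),
        "accuracy": accuracy,
        "interpretation": {
            "importance": importance,
            "pd": pd_curves,
            "ale": ale_curves,
            "h_overall": h_overall,
            "h_pairwise": h_pairwise,
        },
    }
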