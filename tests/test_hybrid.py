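import math

import numpy as np
import pytest

from eirmix.data_prep import preprocess
from eirmix.errors import ParameterError
from eirmix.forest import ForestParams
from eirmix.glmm import LOGISTIC_VARIANCE, fit_crossed_logit
from eirmix.hybrid import (EirmRfFit, fit_eirm_rf, make_target_outcome,
                           predict_eirm_rf, unexplained_variability)
from eirmix.simulate import (SimulationSpec, gen_eirm_dataset, gen_predictors,
                             linear_predictor)


class TestMakeTargetOutcome:
    def test_aligned_cases_keep_original_response(self):
        rng = np.random.default_rng(0)
        out = make_target_outcome([1, 0], [0.9, 0.2], rng)
        np.testing.assert_array_equal(out, [1, 0])

    def test_disagreement_band_is_bernoulli_in_p(self):
        rng = np.random.default_rng(1)
        p = np.full(10_000, 0.9)
        y = np.zeros(10_000)  # v = 0.9 in the probabilistic band
        draws = make_target_outcome(y, p, rng)
        se = math.sqrt(0.9 * 0.1 / 10_000)
        assert abs(draws.mean() - 0.9) < 3 * se

    def test_boundary_values_of_combined_score(self):
        rng = np.random.default_rng(2)
        # v = y + p: 0.4 -> deterministic 0; 1.6 -> deterministic 1
        out = make_target_outcome([0, 1], [0.4, 0.6], rng)
        # middle band (v in [0.5, 1.5]) exercises the random branch
        mid = make_target_outcome(np.zeros(1000), np.full(1000, 0.5), rng)
        assert out[1] == 1
        assert set(np.unique(mid)) <= {0, 1}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            make_target_outcome([0], [1.2], np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_prepared():
    spec = SimulationSpec(n_persons=40, n_items=6, sigma2_person=0.7,
                          sigma2_item=0.7)
    pdf, idf, schema, _ = gen_predictors(spec, seed=31)
    eta, _ = linear_predictor(pdf, idf, schema, "simple", seed=32)
    table = gen_eirm_dataset(pdf, idf, schema, eta, 0.7, 0.7, seed=33)
    return preprocess(table)


class TestFitEirmRf:
    def test_seeded_runs_are_bit_identical(self, small_prepared):
        params = ForestParams(mtry=3, n_trees=60)
        kw = dict(max_iter=3, seed=5, glmm_kwargs={"refine_beta": False})
        a = fit_eirm_rf(small_prepared, params, **kw)
        b = fit_eirm_rf(small_prepared, params, **kw)
        assert a.trace == b.trace
        np.testing.assert_array_equal(a.fitted_prob, b.fitted_prob)

    def test_trace_is_oob_brier_in_unit_interval(self, small_prepared):
        fit = fit_eirm_rf(small_prepared, ForestParams(mtry=3, n_trees=60),
                          max_iter=3, seed=5,
                          glmm_kwargs={"refine_beta": False})
        assert len(fit.trace) == fit.n_iter
        assert all(0 <= t <= 1 for t in fit.trace)
        if fit.converged:
            assert abs(fit.trace[-1] - fit.trace[-2]) < 1e-4

    def test_single_class_response_rejected(self, small_prepared):
        prep = small_prepared
        bad = prep.table.df.copy()
        bad["response"] = 1
        from eirmix.data_prep import ResponseTable
        prep2 = preprocess(ResponseTable(df=bad, schema=prep.table.schema),
                           center=False)
        with pytest.raises(ParameterError):
            fit_eirm_rf(prep2, ForestParams(mtry=2, n_trees=10))

    def test_zero_variance_truth_yields_boundary_variances(self):
        # strong fixed signal, no random effects: the mixed-model step should
        # push both variances to (or near) the boundary at zero
        spec = SimulationSpec(n_persons=60, n_items=8, sigma2_person=0.0,
                              sigma2_item=0.0)
        pdf, idf, schema, _ = gen_predictors(spec, seed=77)
        eta, _ = linear_predictor(pdf, idf, schema, "simple", seed=78)
        hits = 0
        for seed in (1, 2, 3):
            table = gen_eirm_dataset(pdf, idf, schema, 2.0 * eta, 0.0, 0.0,
                                     seed=700 + seed)
            prep = preprocess(table)
            fit = fit_eirm_rf(prep, ForestParams(mtry=4, n_trees=80),
                              max_iter=2, seed=seed,
                              glmm_kwargs={"refine_beta": False})
            if (fit.glmm.sigma2_person < 0.1 and fit.glmm.sigma2_item < 0.1):
                hits += 1
        assert hits >= 2

    def test_intercept_only_reduction_when_forest_is_constant(
            self, small_prepared, monkeypatch):
        # constant forest output leaves the slope unidentified: the hybrid
        # must fall back to the intercept-only crossed model with gamma1 = 0
        import eirmix.hybrid as hyb
        prep = small_prepared
        y = prep.table.y
        pc, _ = prep.table.person_codes()
        ic, _ = prep.table.item_codes()

        class ConstantForest:
            feature_names = prep.schema.names
            oob_error = 0.25
            gini_importance = np.zeros(len(prep.schema.names))

            def train_prob(self, prefer_oob=True):
                return np.full(len(y), 0.5)

        monkeypatch.setattr(hyb, "fit_forest",
                            lambda *a, **k: ConstantForest())
        fit = hyb.fit_eirm_rf(prep, ForestParams(mtry=2, n_trees=10),
                              max_iter=2, seed=0,
                              glmm_kwargs={"refine_beta": False})
        oracle = fit_crossed_logit(y, np.ones((len(y), 1)), pc, ic,
                                   refine_beta=False)
        assert fit.gamma1 == 0.0
        assert fit.gamma0 == pytest.approx(oracle.beta[0], abs=1e-8)
        assert fit.glmm.sigma2_person == pytest.approx(oracle.sigma2_person,
                                                       rel=1e-4, abs=1e-8)


@pytest.fixture(scope="module")
def fit(small_prepared):
    return fit_eirm_rf(small_prepared, ForestParams(mtry=3, n_trees=60),
                       max_iter=2, seed=9,
                       glmm_kwargs={"refine_beta": False})


class TestPredictEirmRf:
    def test_null_composition_gives_half(self, fit, small_prepared):
        import dataclasses
        null_glmm = dataclasses.replace(
            fit.glmm, beta=np.array([0.0, 0.0]),
            person_modes=np.zeros_like(fit.glmm.person_modes),
            item_modes=np.zeros_like(fit.glmm.item_modes))
        null = dataclasses.replace(fit, glmm=null_glmm)
        rows = small_prepared.table.df.iloc[:5]
        assert np.allclose(predict_eirm_rf(null, rows), 0.5)

    def test_fixed_part_identical_for_matching_features(self, fit, small_prepared):
        rows = small_prepared.table.df.iloc[[0]].copy()
        twin = rows.copy()
        twin["person_id"] = "someone-new"
        p1 = predict_eirm_rf(fit, rows, include_random=False)
        p2 = predict_eirm_rf(fit, twin, include_random=False)
        assert p1[0] == pytest.approx(p2[0], abs=1e-12)

    def test_monotone_in_forest_probability_when_slope_positive(
            self, fit, small_prepared):
        import dataclasses
        glmm = dataclasses.replace(
            fit.glmm, beta=np.array([0.0, 2.0]),
            person_modes=np.zeros_like(fit.glmm.person_modes),
            item_modes=np.zeros_like(fit.glmm.item_modes))
        mono = dataclasses.replace(fit, glmm=glmm)
        rows = small_prepared.table.df.iloc[:20]
        from eirmix.data_prep import encode
        feats, _ = encode(small_prepared, mode="forest", df=rows)
        p_rf = fit.forest.predict_prob(feats)
        pred = predict_eirm_rf(mono, rows, include_random=False)
        order = np.argsort(p_rf)
        assert np.all(np.diff(pred[order]) >= -1e-12)


def fit_stub(s2p, s2i, gamma1):
    from eirmix.glmm import GlmmFit
    return GlmmFit(
        beta=np.array([0.0, gamma1]), beta_cov=np.eye(2), se=np.ones(2),
        sigma2_person=s2p, sigma2_item=s2i,
        person_modes=np.zeros(1), item_modes=np.zeros(1),
        laplace_loglik=0.0, converged=True, boundary=False,
        n_inner_iters=1, n_outer_iters=1, beta_names=["gamma0", "gamma1"])


class TestUnexplainedVariability:
    def _fit_with(self, var_explained, s2p, s2i, gamma1=1.0):
        # p_rf chosen so Var(gamma1 * p_rf) equals var_explained exactly
        half = math.sqrt(var_explained)
        p_rf = np.array([-half, half]) / gamma1 + 0.5
        glmm = fit_stub(s2p, s2i, gamma1)
        return EirmRfFit(
            forest=None, glmm=glmm, fitted_prob=np.array([0.5, 0.5]),
            p_rf=p_rf, trace=[0.1], n_iter=1, converged=True, seeds={},
            person_ids=[], item_ids=[], prepared=None)

    def test_default_definition_direct_arithmetic(self):
        fit = self._fit_with(2.0, 0.7, 0.7)
        expected = (1.4 + LOGISTIC_VARIANCE) / (2.0 + 1.4 + LOGISTIC_VARIANCE)
        assert unexplained_variability(fit) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.70104, abs=5e-5)

    def test_nothing_explained_gives_one(self):
        fit = self._fit_with(0.0, 0.0, 0.0)
        assert unexplained_variability(fit) == pytest.approx(1.0)

    def test_vanishes_as_explained_variance_grows(self):
        small = unexplained_variability(self._fit_with(1e6, 0.7, 0.7))
        assert small < 1e-4

    def test_unknown_definition_rejected(self):
        fit = self._fit_with(1.0, 0.1, 0.1)
        with pytest.raises(ParameterError):
            unexplained_variability(fit, definition="bogus")

    def test_random_only_definition(self):
        fit = self._fit_with(1.0, 0.7, 0.7)
        expected = 1.4 / (1.4 + LOGISTIC_VARIANCE)
        assert unexplained_variability(fit, "random_only") == pytest.approx(expected)
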