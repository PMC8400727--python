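"""Module interpretation: local surrogates, forest importance, the age
regression, and gene-set overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from jdsnmf import (
    age_regression,
    importance_vs_pathway_regression,
    local_surrogate_importance,
    overlap_fisher,
    rf_module_importance,
)
from jdsnmf.exceptions import ConfigurationError, DegenerateInputError, DegenerateTestError
from oracles import hypergeom_two_sided


class TestLocalSurrogate:
    @pytest.fixture(scope="class")
    def linear_setup(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(150, 8))
        coefs = np.array([3.0, 0.0, -2.0, 0.0, 1.0, 0.0, 0.0, 0.5])
        return X, coefs, (lambda Z: expit(np.asarray(Z) @ coefs))

    def test_recovers_linear_coefficient_profile(self, linear_setup):
        X, coefs, pf = linear_setup
        rep = local_surrogate_importance(pf, X, instances=np.arange(25),
                                         n_perturbations=400, seed=1)
        cos = np.dot(rep.weights, np.abs(coefs)) / (
            np.linalg.norm(rep.weights) * np.linalg.norm(coefs)
        )
        assert cos > 0.95
        # ranking of |coefficients| is recovered
        assert rep.top_module == 0

    def test_constant_feature_gets_no_weight(self, linear_setup):
        X, coefs, pf = linear_setup
        Xc = X.copy()
        Xc[:, 1] = 7.0  # zero-variance feature
        rep = local_surrogate_importance(pf, Xc, instances=np.arange(10),
                                         n_perturbations=300, seed=2)
        assert rep.weights[1] <= 0.05 * rep.weights.max()

    def test_seeded_determinism(self, linear_setup):
        X, _, pf = linear_setup
        a = local_surrogate_importance(pf, X, instances=np.arange(5),
                                       n_perturbations=100, seed=7)
        b = local_surrogate_importance(pf, X, instances=np.arange(5),
                                       n_perturbations=100, seed=7)
        assert np.array_equal(a.weights, b.weights)

    def test_constant_predictor_warns(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.warns(UserWarning):
            rep = local_surrogate_importance(lambda Z: np.full(len(Z), 0.5), X,
                                             instances=[0], n_perturbations=50)
        assert np.all(rep.weights == 0)

    def test_ranks_are_permutation(self, linear_setup):
        X, _, pf = linear_setup
        rep = local_surrogate_importance(pf, X, instances=np.arange(5),
                                         n_perturbations=100, seed=0)
        assert sorted(rep.rank) == list(range(X.shape[1]))


class TestForestImportance:
    def test_importances_normalized_and_signal_found(self, rng):
        y = np.repeat([0, 1], 60)
        X = rng.normal(size=(120, 6))
        X[:, 3] += 3.0 * y
        imp = rf_module_importance(X, y, seed=0, n_estimators=200)
        assert imp.sum() == pytest.approx(1.0)
        assert imp.argmax() == 3

    def test_pure_noise_roughly_uniform(self, rng):
        y = np.tile([0, 1], 50)
        imps = np.zeros(5)
        for s in range(10):
            X = np.random.default_rng(s).normal(size=(100, 5))
            imps += rf_module_importance(X, y, seed=s, n_estimators=100)
        imps /= 10
        assert np.all(np.abs(imps - 0.2) < 0.1)


class TestAgeRegression:
    def make_cov(self, rng, n):
        return pd.DataFrame({
            "age": rng.uniform(55, 95, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "diagnosis": rng.integers(0, 2, n).astype(float),
        })

    def test_planted_coefficient_recovered(self, rng):
        n = 200
        cov = self.make_cov(rng, n)
        Y = np.column_stack([
            2.0 * cov["age"].to_numpy() + rng.normal(0, 0.1, n),
            rng.normal(size=n),
        ])
        res = age_regression(Y, cov)
        assert 1.8 <= res[0].gamma <= 2.2
        assert res[0].p_value < 1e-6
        assert res[0].gamma > 0  # positive association flagged by sign

    def test_negative_association_sign(self, rng):
        n = 150
        cov = self.make_cov(rng, n)
        Y = (-1.5 * cov["age"].to_numpy() + rng.normal(0, 0.5, n))[:, None]
        res = age_regression(Y, cov)
        assert res[0].gamma < 0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, n_modules = 200, 1000
        cov = self.make_cov(rng, n)
        Y = rng.normal(size=(n, n_modules))
        res = age_regression(Y, cov)
        frac = np.mean([r.p_value < 0.05 for r in res])
        se = math.sqrt(0.05 * 0.95 / n_modules)
        assert abs(frac - 0.05) <= 4 * se

    def test_constant_diagnosis_dropped_with_warning(self, rng):
        n = 80
        cov = self.make_cov(rng, n)
        cov["diagnosis"] = 1.0
        with pytest.warns(UserWarning):
            res = age_regression(rng.normal(size=(n, 2)), cov)
        assert res[0].diagnosis_coef is None

    def test_misaligned_covariates_rejected(self, rng):
        cov = self.make_cov(rng, 30)
        with pytest.raises(ConfigurationError):
            age_regression(rng.normal(size=(20, 2)), cov)


class TestOverlapFisher:
    def test_complete_overlap_is_extreme(self):
        universe = [f"g{i}" for i in range(500)]
        module = universe[:40]
        _, p = overlap_fisher(module, module, universe)
        assert p < 1e-20

    def test_matches_hypergeometric_enumeration(self):
        universe = [f"g{i}" for i in range(16)]
        module = universe[:10]          # a + b = 10
        reference = universe[:8] + universe[10:11]  # a = 8, c = 1
        odds, p = overlap_fisher(module, reference, universe)
        assert p == pytest.approx(hypergeom_two_sided(8, 2, 1, 5), rel=1e-9)

    def test_null_calibration_uniformish(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(200)]
        ps = []
        for _ in range(200):
            module = rng.choice(universe, 30, replace=False)
            ref = rng.choice(universe, 40, replace=False)
            ps.append(overlap_fisher(module, ref, universe)[1])
        assert np.mean(np.array(ps) < 0.05) < 0.1  # conservative discrete test

    def test_empty_universe_rejected(self):
        with pytest.raises(DegenerateInputError):
            overlap_fisher(["a"], ["a"], [])


class TestImportancePathwayRegression:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, slope = importance_vs_pathway_regression(x, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _, _ = importance_vs_pathway_regression(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_dataset_matches_covariance_formula(self):
        x = np.array([1.0, 3.0, 4.0, 6.0, 8.0])
        y = np.array([2.0, 3.0, 7.0, 5.0, 9.0])
        r, _, slope = importance_vs_pathway_regression(x, y)
        rx = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(rx, rel=1e-12)
        assert slope == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateTestError):
            importance_vs_pathway_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
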