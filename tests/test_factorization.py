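"""Core decomposition: activations, reconstruction, objective, init, fit."""

import numpy as np
import pytest
from scipy.special import expit

from jdsnmf import (
    JDSNMF,
    DataBlock,
    FactorModel,
    ModelConfig,
    apply_activation,
    extract_features,
    fit,
    layer_latents,
    objective,
    reconstruct_block,
    svd_initialize,
)
from jdsnmf.exceptions import ConfigurationError, DegenerateInputError
from oracles import brute_force_reconstruction


def random_model(rng, c=6, m=5, dims=(4, 3), activation="sigmoid", n_blocks=1):
    config = ModelConfig(dims=dims, activation=activation)
    U = rng.normal(size=(c, dims[0]))
    Z = [[rng.normal(size=(dims[n - 1], dims[n])) for n in range(1, len(dims))]
         for _ in range(n_blocks)]
    H = [rng.normal(size=(dims[-1], m)) for _ in range(n_blocks)]
    return FactorModel(U=U, Z=Z, H_deep=H, config=config)


class TestActivation:
    def test_sigmoid_of_zero_is_half(self):
        assert np.allclose(apply_activation(np.zeros((3, 2)), "sigmoid"), 0.5)

    def test_relu_definition(self):
        out = apply_activation(np.array([[-2.0, 3.0]]), "relu")
        assert np.array_equal(out, [[0.0, 3.0]])

    def test_sigmoid_monotone_and_symmetric(self):
        out = apply_activation(np.array([[-1.0, 0.0, 1.0]]), "sigmoid")
        assert np.all(np.diff(out[0]) > 0)
        assert out[0, 0] + out[0, 2] == pytest.approx(1.0)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_activation(np.zeros((2, 2)), "tanh")


class TestReconstruction:
    def test_identity_activation_composes_linearly(self, rng):
        model = random_model(rng, activation="identity")
        expected = model.U @ model.Z[0][0] @ model.H_deep[0]
        assert np.allclose(reconstruct_block(model, 0), expected)

    def test_zero_junction_gives_constant_columns(self, rng):
        model = random_model(rng, activation="sigmoid")
        model.Z[0][0] = np.zeros_like(model.Z[0][0])
        recon = reconstruct_block(model, 0)
        expected_col = 0.5 * model.U.sum(axis=1)
        assert np.allclose(recon, expected_col[:, None])

    @pytest.mark.parametrize("dims", [(4, 3), (5, 4, 2), (6, 4, 3, 2)])
    def test_matches_nested_loop_oracle(self, rng, dims):
        model = random_model(rng, c=4, m=3, dims=dims)
        assert np.max(np.abs(reconstruct_block(model, 0) - brute_force_reconstruction(model, 0))) < 1e-10

    def test_derived_layers_nonnegative_and_bounded(self, two_block_model):
        _, model, _ = two_block_model
        for i in range(model.n_blocks):
            latents = layer_latents(model, i)
            for h in latents[:-1]:
                assert np.all(h >= 0)
                assert np.all(h < 1)  # sigmoid range


class TestObjective:
    def test_exact_reconstruction_zero_loss(self, rng):
        model = random_model(rng, activation="sigmoid")
        x = reconstruct_block(model, 0)
        total, fits, reg = objective(model, [DataBlock.from_array(x)], 0.0)
        assert total == pytest.approx(0.0, abs=1e-18)
        assert reg == 0.0

    def test_half_grid_residual(self):
        config = ModelConfig(dims=(2, 1), activation="sigmoid")
        model = FactorModel(
            U=np.eye(2), Z=[[np.zeros((2, 1))]], H_deep=[np.zeros((1, 2))], config=config
        )
        total, _, _ = objective(model, [DataBlock.from_array(np.eye(2))], 0.0)
        assert total == pytest.approx(1.0)

    def test_penalty_matches_direct_sum(self, rng):
        model = random_model(rng)
        x = DataBlock.from_array(rng.normal(size=(6, 5)))
        total, fits, reg = objective(model, [x], 0.1)
        direct = sum(
            float(np.sum(s * s))
            for s in [model.U, model.Z[0][0], model.H_deep[0]]
        )
        assert reg == pytest.approx(0.1 * direct, rel=1e-12)
        assert total == pytest.approx(sum(fits) + reg, rel=1e-9)

    def test_negative_lambda_rejected(self, rng):
        model = random_model(rng)
        with pytest.raises(ConfigurationError):
            objective(model, [DataBlock.from_array(rng.normal(size=(6, 5)))], -1.0)


class TestSVDInitialize:
    def test_exact_low_rank_input_reaches_truncation_optimum(self, rng):
        # rank-4 input, bottleneck K1=3: init must equal the rank-3 SVD optimum
        a = rng.normal(size=(20, 4)) @ rng.normal(size=(4, 15))
        blocks = [DataBlock.from_array(a)]
        config = ModelConfig(dims=(4, 3), activation="identity")
        model = svd_initialize(blocks, config)
        s = np.linalg.svd(a, compute_uv=False)
        opt = float(np.sum(s[3:] ** 2))
        total, _, _ = objective(model, blocks, 0.0)
        assert total == pytest.approx(opt, abs=1e-6 * max(opt, 1.0))

    def test_deterministic_and_shapes(self, random_blocks):
        blocks = random_blocks(c=20, ms=(15, 12), seed=3)
        config = ModelConfig(dims=(6, 4, 2))
        m1 = svd_initialize(blocks, config)
        m2 = svd_initialize(blocks, config)
        assert np.array_equal(m1.U, m2.U)
        assert m1.U.shape == (20, 6)
        for i, mcols in enumerate((15, 12)):
            assert m1.Z[i][0].shape == (6, 4)
            assert m1.Z[i][1].shape == (4, 2)
            assert m1.H_deep[i].shape == (2, mcols)
            assert np.array_equal(m1.H_deep[i], m2.H_deep[i])

    def test_beats_median_random_init(self, rng):
        blocks = [DataBlock.from_array(rng.normal(size=(30, 20)))]
        config = ModelConfig(dims=(5, 4))
        init_obj, _, _ = objective(svd_initialize(blocks, config), blocks, 0.0)
        rand_objs = []
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            m = FactorModel(
                U=r.normal(size=(30, 5)),
                Z=[[r.normal(size=(5, 4))]],
                H_deep=[r.normal(size=(4, 20))],
                config=config,
            )
            rand_objs.append(objective(m, blocks, 0.0)[0])
        assert init_obj <= np.median(rand_objs)

    def test_constant_block_rejected(self):
        with pytest.warns(UserWarning):
            blocks = [DataBlock.from_array(np.ones((10, 8)))]
        with pytest.raises(DegenerateInputError):
            svd_initialize(blocks, ModelConfig(dims=(3, 2)))


class TestFit:
    def test_semi_nmf_special_case_reaches_svd_optimum(self):
        r = np.random.default_rng(42)
        x = r.normal(size=(50, 40))
        config = ModelConfig(
            dims=(6, 5), activation="identity", learning_rate=0.01,
            max_epochs=300, patience=100, seed=0,
        )
        model, _ = fit([DataBlock.from_array(x)], config)
        s = np.linalg.svd(x, compute_uv=False)
        opt = float(np.sum(s[5:] ** 2))
        total, _, _ = objective(model, [DataBlock.from_array(x)], 0.0)
        assert total <= 1.05 * opt

    def test_regularization_shrinks_factor_norms(self, random_blocks):
        blocks = random_blocks(c=20, ms=(15,), seed=11)
        def norms(model):
            return (np.sum(model.U**2) + np.sum(model.Z[0][0]**2)
                    + np.sum(model.H_deep[0]**2))
        base = dict(dims=(4, 3), learning_rate=0.01, max_epochs=200, patience=50, seed=1)
        m_free, _ = fit(blocks, ModelConfig(l2_lambda=0.0, **base))
        m_reg, _ = fit(blocks, ModelConfig(l2_lambda=1e3, **base))
        assert norms(m_reg) < norms(m_free)

    def test_seed_determinism(self, random_blocks):
        blocks = random_blocks(c=15, ms=(12,), seed=5)
        config = ModelConfig(dims=(4, 2), max_epochs=100, learning_rate=0.01)
        m1, t1 = fit(blocks, config)
        m2, t2 = fit(blocks, config)
        assert m1.loss_trace == m2.loss_trace
        assert np.array_equal(m1.U, m2.U)

    def test_running_minimum_of_trace_is_monotone(self, two_block_model):
        _, model, traces = two_block_model
        running = np.minimum.accumulate([t.total_loss for t in traces])
        assert np.all(np.diff(running) <= 0)

    def test_trace_decomposition(self, two_block_model):
        _, _, traces = two_block_model
        for t in traces[::50]:
            assert t.total_loss == pytest.approx(sum(t.per_block_loss) + t.reg_loss, rel=1e-9)

    def test_best_epoch_not_after_last(self, two_block_model):
        _, _, traces = two_block_model
        assert traces[-1].best_epoch <= traces[-1].epoch


class TestExtractFeatures:
    def test_feature_matched_shapes_and_nonnegativity(self, two_block_model):
        _, model, _ = two_block_model
        feats = extract_features(model, layer=0, block=0, mode="feature_matched")
        assert feats.shape == (24, 5)
        assert np.all(feats >= 0)

    def test_sample_matched_returns_u_rows(self, two_block_model):
        _, model, _ = two_block_model
        feats = extract_features(model, mode="sample_matched")
        assert feats.shape == (30, 5)
        assert np.array_equal(feats, model.U)

    def test_deepest_layer_equals_stored_latent(self, two_block_model):
        _, model, _ = two_block_model
        feats = extract_features(model, layer=model.n_layers, block=1, mode="feature_matched")
        assert np.array_equal(feats, model.H_deep[1].T)

    def test_layer_out_of_range(self, two_block_model):
        _, model, _ = two_block_model
        with pytest.raises(IndexError):
            extract_features(model, layer=model.n_layers + 1, block=0, mode="feature_matched")


class TestEstimator:
    def test_get_set_params_roundtrip(self):
        est = JDSNMF(dims=(4, 2), l2_lambda=0.5)
        params = est.get_params()
        assert params["l2_lambda"] == 0.5
        est.set_params(l2_lambda=0.1)
        assert est.l2_lambda == 0.1

    def test_fit_transform_shape(self, rng):
        X = rng.normal(size=(25, 18))
        feats = JDSNMF(dims=(4, 2), max_epochs=100, mode="sample_matched").fit_transform([X])
        assert feats.shape == (25, 4)
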