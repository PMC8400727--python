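import numpy as np
import pytest

from jdsnmf import DataBlock, ModelConfig, fit, simulate_from_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_block_model():
    """A small two-block model fitted once and shared across tests."""
    blocks, truth = simulate_from_model(
        C=30, M_list=[24, 18], dims=(5, 3), activation="sigmoid", noise_sd=0.05, seed=7
    )
    config = ModelConfig(
        dims=(5, 3), activation="sigmoid", learning_rate=0.02,
        max_epochs=400, patience=100, seed=7,
    )
    model, traces = fit(blocks, config)
    return blocks, model, traces


@pytest.fixture
def random_blocks(rng):
    def make(c=20, ms=(15,), seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return [DataBlock.from_array(r.normal(size=(c, m)), name=f"b{i}")
                for i, m in enumerate(ms)]
    return make
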