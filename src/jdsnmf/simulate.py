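"""Synthetic benchmark generators.

Two families:

* a multi-view logistic benchmark — each view draws an i.i.d. standard
  normal predictor matrix and a sparse coefficient vector (20 entries of
  +/-10 among 1000 by default), with class probability
  y_s = expit(beta_0 + x_s . beta + eps_s), eps ~ N(0, 1.6 variance), and
  samples kept only when their hard labels agree across all views;

* a generative-recovery benchmark that draws ground-truth factors of the
  layered decomposition and emits X_i = U g(Z_i ... H_i) + noise, so the
  generator itself is the oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .datatypes import DataBlock, FactorModel, ModelConfig
from .exceptions import ConfigurationError, DegenerateInputError
from .factorization import reconstruct_block

__all__ = ["SimulationDesign", "MultiViewSample", "simulate_view", "simulate_multiview",
           "simulate_from_model", "reference_design"]


@dataclass
class SimulationDesign:
    """Parameters of the logistic multi-view benchmark.

    Defaults reproduce the published study conditions: 1000 features of
    which 20 carry coefficients +/-10, error variance 1.6, three views, and
    a 750/50/100 train/validation/test split.
    """

    n_features: int = 1000
    n_informative: int = 20
    coef_magnitude: float = 10.0
    noise_variance: float = 1.6
    n_train: int = 750
    n_valid: int = 50
    n_test: int = 100
    n_views: int = 3
    intercept: float = 0.0
    label_rule: str = "threshold"  # or "bernoulli"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative cannot exceed n_features")
        if self.coef_magnitude <= 0:
            raise ConfigurationError("coef_magnitude must be positive")
        if self.noise_variance < 0:
            raise ConfigurationError("noise_variance must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_train + self.n_valid + self.n_test

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MultiViewSample:
    """Views with shared sample ids and consistent labels, plus the split."""

    views: list[np.ndarray]
    betas: list[np.ndarray]
    labels: np.ndarray
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    design: SimulationDesign = field(default=None)  # type: ignore[assignment]

    def split(self, which: str) -> np.ndarray:
        return {"train": self.train_idx, "valid": self.valid_idx, "test": self.test_idx}[which]


def _draw_beta(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    beta = np.zeros(design.n_features)
    idx = rng.choice(design.n_features, size=design.n_informative, replace=False)
    beta[idx] = rng.choice([-1.0, 1.0], size=design.n_informative) * design.coef_magnitude
    return beta


def _labels_from(design, X, beta, rng) -> tuple[np.ndarray, np.ndarray]:
    eps = rng.normal(0.0, np.sqrt(design.noise_variance), size=X.shape[0])
    prob = expit(design.intercept + X @ beta + eps)
    if design.label_rule == "bernoulli":
        y = (rng.random(X.shape[0]) < prob).astype(int)
    else:
        y = (prob > 0.5).astype(int)
    return prob, y


def simulate_view(
    design: SimulationDesign, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One view: predictors X (S x F), sparse beta, and hard labels y."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    X = rng.normal(size=(design.n_samples, design.n_features))
    beta = _draw_beta(design, rng)
    _, y = _labels_from(design, X, beta, rng)
    return X, beta, y


def simulate_multiview(design: SimulationDesign, seed: int | None = None) -> MultiViewSample:
    """Views with labels made consistent by rejection sampling.

    Candidate samples are drawn in batches for every view simultaneously
    and kept only when all views assign them the same hard label, until the
    requested train+valid+test count accumulates.
    """
    if design.n_views < 2:
        raise ConfigurationError("need at least 2 views")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    betas = [_draw_beta(design, rng) for _ in range(design.n_views)]
    need = design.n_samples
    kept_X: list[list[np.ndarray]] = [[] for _ in range(design.n_views)]
    kept_y: list[np.ndarray] = []
    drawn = accepted = 0
    batch = max(4 * need, 256)
    while accepted < need:
        xs, ys = [], []
        for v in range(design.n_views):
            X = rng.normal(size=(batch, design.n_features))
            _, y = _labels_from(design, X, betas[v], rng)
            xs.append(X)
            ys.append(y)
        agree = np.all(np.stack(ys) == ys[0], axis=0)
        drawn += batch
        accepted += int(agree.sum())
        for v in range(design.n_views):
            kept_X[v].append(xs[v][agree])
        kept_y.append(ys[0][agree])
        if drawn >= 64 * need and accepted < max(1, drawn * 1e-3):
            raise DegenerateInputError(
                "label-consistency acceptance rate below 1e-3; "
                "increase coef_magnitude or reduce the number of views"
            )
    views = [np.concatenate(kx)[:need] for kx in kept_X]
    labels = np.concatenate(kept_y)[:need]
    idx = np.arange(need)
    return MultiViewSample(
        views=views,
        betas=betas,
        labels=labels,
        train_idx=idx[: design.n_train],
        valid_idx=idx[design.n_train : design.n_train + design.n_valid],
        test_idx=idx[design.n_train + design.n_valid :],
        design=design,
    )


def simulate_from_model(
    C: int,
    M_list: list[int],
    dims: tuple[int, ...],
    activation: str = "sigmoid",
    noise_sd: float = 0.01,
    seed: int = 0,
    factor_scale: float = 1.0,
) -> tuple[list[DataBlock], FactorModel]:
    """Blocks generated from known factors, for recovery tests.

    Draws U, junction matrices and deepest latents from N(0, factor_scale),
    composes X_i = U g(...) and adds N(0, noise_sd) noise.  Returns both
    the blocks and the ground-truth model.
    """
    rng = np.random.default_rng(seed)
    config = ModelConfig(dims=tuple(dims), activation=activation, seed=seed)
    U = rng.normal(scale=factor_scale, size=(C, dims[0]))
    Z = [
        [rng.normal(scale=factor_scale, size=(dims[n - 1], dims[n])) for n in range(1, len(dims))]
        for _ in M_list
    ]
    H = [rng.normal(scale=factor_scale, size=(dims[-1], m)) for m in M_list]
    truth = FactorModel(U=U, Z=Z, H_deep=H, config=config,
                        block_names=[f"block{i}" for i in range(len(M_list))])
    blocks = []
    for i, m in enumerate(M_list):
        x = reconstruct_block(truth, i)
        if noise_sd > 0:
            x = x + rng.normal(scale=noise_sd, size=x.shape)
        blocks.append(DataBlock.from_array(x, name=f"block{i}"))
    return blocks, truth


def reference_design(seed: int = 0, **overrides) -> SimulationDesign:
    """The published benchmark conditions, optionally overridden."""
    return SimulationDesign(seed=seed, **overrides)
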