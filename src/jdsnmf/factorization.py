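"""Joint deep semi-non-negative matrix factorization.

Given blocks X_1 (C x M_1), ..., X_I (C x M_I) that share their row entities,
the model decomposes every block around one shared mixed-sign latent matrix
U (C x K_0) and a per-block hierarchy of junction matrices Z_i^n and a
deepest free latent H_i^N:

    X_i  ~=  U g(Z_i^1 g(Z_i^2 ... g(Z_i^N H_i^N)))

with elementwise activation g (sigmoid by default), so every derived layer
latent H_i^{n-1} = g(Z_i^n H_i^n) is non-negative without any projection
step.  The objective is the summed squared Frobenius reconstruction error
plus an L2 penalty on every free factor:

    L = sum_i || X_i - U g(...) ||_F^2
        + lambda * sum_{S in {U, Z_i^n, H_i^N}} || S ||_F^2

minimised by Adam from a deterministic SVD initialization, with early
stopping on the training objective and best-snapshot restore.

Setting I = 1 recovers a deep semi-NMF; I = 1, N = 1 with the identity
activation recovers plain semi-NMF (whose optimum coincides with the
truncated SVD of X, a useful correctness oracle).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import DataBlock, FactorModel, ModelConfig, TrainingTrace
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    OptimizationError,
    ShapeError,
)

__all__ = [
    "JDSNMF",
    "apply_activation",
    "activation_grad",
    "layer_latents",
    "reconstruct_block",
    "objective",
    "svd_initialize",
    "fit",
    "extract_features",
]


# ---------------------------------------------------------------------------
# activations


def apply_activation(M: np.ndarray, kind: str) -> np.ndarray:
    """Apply the activation g elementwise.

    ``sigmoid`` maps into (0, 1), ``relu`` into [0, inf).  ``identity`` is a
    linear test hook that recovers the classical (deep) semi-NMF family; it
    does not enforce non-negativity.
    """
    M = np.asarray(M, dtype=float)
    if kind == "sigmoid":
        return expit(M)
    if kind == "relu":
        return np.maximum(M, 0.0)
    if kind == "identity":
        return M
    raise ConfigurationError(f"unsupported activation {kind!r}")


def activation_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    """g'(pre), reusing the already-computed g(pre) where cheap."""
    if kind == "sigmoid":
        return post * (1.0 - post)
    if kind == "relu":
        return (pre > 0).astype(float)
    if kind == "identity":
        return np.ones_like(pre)
    raise ConfigurationError(f"unsupported activation {kind!r}")


# ---------------------------------------------------------------------------
# forward passes


def layer_latents(model: FactorModel, i: int) -> list[np.ndarray]:
    """All layer latents [H_i^0, ..., H_i^N] for block ``i``.

    H_i^N is the stored free parameter; each shallower layer is derived as
    H^{n-1} = g(Z^n H^n), hence non-negative for sigmoid/relu activations.
    """
    act = model.config.activation
    latents = [model.H_deep[i]]
    for z in reversed(model.Z[i]):
        latents.append(apply_activation(z @ latents[-1], act))
    latents.reverse()
    return latents


def reconstruct_block(model: FactorModel, i: int) -> np.ndarray:
    """U g(Z_i^1 g(Z_i^2 ... g(Z_i^N H_i^N))) for block ``i``."""
    h = model.H_deep[i]
    act = model.config.activation
    for n in range(len(model.Z[i]), 0, -1):
        z = model.Z[i][n - 1]
        if z.shape[1] != h.shape[0]:
            raise ShapeError(
                f"block {i}, layer {n}: Z ({z.shape[0]}x{z.shape[1]}) does not "
                f"compose with latent ({h.shape[0]}x{h.shape[1]})"
            )
        h = apply_activation(z @ h, act)
    if model.U.shape[1] != h.shape[0]:
        raise ShapeError(
            f"block {i}: U ({model.U.shape[0]}x{model.U.shape[1]}) does not "
            f"compose with first-layer latent ({h.shape[0]}x{h.shape[1]})"
        )
    return model.U @ h


def objective(
    model: FactorModel, blocks: list[DataBlock], l2_lambda: float | None = None
) -> tuple[float, list[float], float]:
    """Total objective, per-block fit terms and the L2 penalty term.

    The penalty covers exactly the free factors: U, every Z_i^n and every
    deepest latent H_i^N (squared Frobenius norms).
    """
    lam = model.config.l2_lambda if l2_lambda is None else float(l2_lambda)
    if lam < 0:
        raise ConfigurationError("l2_lambda must be non-negative")
    fit_terms = []
    for i, block in enumerate(blocks):
        resid = block.values - reconstruct_block(model, i)
        fit_terms.append(float(np.sum(resid * resid)))
    reg = 0.0
    if lam > 0:
        reg = float(np.sum(model.U * model.U))
        for i in range(model.n_blocks):
            for z in model.Z[i]:
                reg += float(np.sum(z * z))
            reg += float(np.sum(model.H_deep[i] * model.H_deep[i]))
        reg *= lam
    return sum(fit_terms) + reg, fit_terms, reg


# ---------------------------------------------------------------------------
# initialization


def _sign_fix(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|entry| of each left singular
    vector made positive, compensated in the right factor."""
    flips = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flips[flips == 0] = 1.0
    return u * flips, vt * flips[:, None]


def svd_initialize(
    blocks: list[DataBlock], config: ModelConfig, refit_U: bool = True
) -> FactorModel:
    """Deterministic SVD initialization of all free factors.

    The shared latent U takes the first K_0 left singular vectors of the
    column-concatenation [X_1 | ... | X_I], scaled by the singular values;
    each block's first-layer latent starts from its slice of the right
    factor.  Deeper layers are initialized by recursive truncated SVD of the
    layer latent, weighted by the current left-stack column norms so that in
    the identity-activation case the composition equals the truncated SVD of
    the input at the bottleneck rank.
    """
    config.validate_against(blocks)
    xcat = np.concatenate([b.values for b in blocks], axis=1)
    if np.ptp(xcat) == 0.0:
        raise DegenerateInputError("all blocks are constant; SVD initialization is undefined")
    for b in blocks:
        if np.ptp(b.values) == 0.0:
            raise DegenerateInputError(f"block {b.name!r} is constant")
    k0 = config.dims[0]
    if k0 >= min(xcat.shape):
        raise ConfigurationError(
            f"K0={k0} must be smaller than min(C, sum_i M_i)={min(xcat.shape)}"
        )
    u_full, s, vt = np.linalg.svd(xcat, full_matrices=False)
    u_full, vt = _sign_fix(u_full, vt)
    U = u_full[:, :k0] * s[:k0]
    h0_cat = vt[:k0]

    eps = 1e-12 * max(1.0, float(s[0]))
    Z_all: list[list[np.ndarray]] = []
    H_deep: list[np.ndarray] = []
    offset = 0
    for b in blocks:
        m = b.shape[1]
        r = h0_cat[:, offset : offset + m]
        offset += m
        w = np.maximum(s[:k0], eps)
        z_list: list[np.ndarray] = []
        for n in range(1, config.n_layers + 1):
            k = config.dims[n]
            p, sig, qt = np.linalg.svd(w[:, None] * r, full_matrices=False)
            p, qt = _sign_fix(p, qt)
            z_list.append((p[:, :k] * sig[:k]) / w[:, None])
            r = qt[:k]
            w = np.maximum(sig[:k], eps)
        Z_all.append(z_list)
        H_deep.append(r.copy())  # scale lives in the last junction matrix
    if refit_U:
        # Refit U by least squares against the *activated* first-layer
        # latents: the recursion above is exact for the identity activation
        # (keeping the Eckart–Young optimum) but a non-linear activation
        # rescales the latent, so the best U given the initialized chain is
        # this linear solve.
        probe = FactorModel(U=U, Z=Z_all, H_deep=H_deep, config=config,
                            block_names=[b.name for b in blocks])
        h0_act = np.concatenate(
            [layer_latents(probe, i)[0] for i in range(len(blocks))], axis=1
        )
        U = np.linalg.lstsq(h0_act.T, xcat.T, rcond=None)[0].T
    model = FactorModel(
        U=U,
        Z=Z_all,
        H_deep=H_deep,
        config=config,
        block_names=[b.name for b in blocks],
        row_ids=list(blocks[0].row_ids),
        col_ids=[list(b.col_ids) for b in blocks],
    )
    model.check_shapes()
    return model


# ---------------------------------------------------------------------------
# gradients and Adam


def _loss_and_grads(
    params: dict, blocks: list[DataBlock], config: ModelConfig
) -> tuple[float, list[float], float, dict]:
    """Closed-form gradient of the objective w.r.t. every free factor."""
    act = config.activation
    lam = config.l2_lambda
    U = params["U"]
    grads = {"U": np.zeros_like(U), "Z": [], "H": []}
    fit_terms: list[float] = []
    for i, block in enumerate(blocks):
        z_list = params["Z"][i]
        h = params["H"][i]
        pres, posts = [], []
        for z in reversed(z_list):
            pre = z @ h
            h = apply_activation(pre, act)
            pres.append(pre)
            posts.append(h)
        # posts[-1] is H^0 (or H_deep itself when N == 0)
        h0 = posts[-1] if z_list else params["H"][i]
        recon = U @ h0
        resid = recon - block.values
        fit_terms.append(float(np.sum(resid * resid)))
        grads["U"] += 2.0 * (resid @ h0.T)
        g_h = 2.0 * (U.T @ resid)  # dL/dH^0
        z_grads: list[np.ndarray] = [None] * len(z_list)
        for n in range(1, len(z_list) + 1):
            # walk from layer 1 (shallowest) down to layer N
            pre = pres[len(z_list) - n]
            post = posts[len(z_list) - n]
            d_pre = g_h * activation_grad(pre, post, act)
            h_below = posts[len(z_list) - n - 1] if n < len(z_list) else params["H"][i]
            z_grads[n - 1] = d_pre @ h_below.T
            g_h = z_list[n - 1].T @ d_pre
        grads["Z"].append(z_grads)
        grads["H"].append(g_h)  # dL/dH^N
    reg = 0.0
    if lam > 0:
        reg += float(np.sum(U * U))
        grads["U"] += 2.0 * lam * U
        for i in range(len(blocks)):
            for n, z in enumerate(params["Z"][i]):
                reg += float(np.sum(z * z))
                grads["Z"][i][n] = grads["Z"][i][n] + 2.0 * lam * z
            h = params["H"][i]
            reg += float(np.sum(h * h))
            grads["H"][i] = grads["H"][i] + 2.0 * lam * h
        reg *= lam
    total = sum(fit_terms) + reg
    return total, fit_terms, reg, grads


class _Adam:
    """Plain Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, key, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if key not in self.m:
            self.m[key] = np.zeros_like(param)
            self.v[key] = np.zeros_like(param)
        m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
        v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad * grad
        mhat = m / (1 - self.b1**self.t)
        vhat = v / (1 - self.b2**self.t)
        return param - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _adam_run(model: FactorModel, blocks: list[DataBlock], config: ModelConfig):
    params = {"U": model.U, "Z": model.Z, "H": model.H_deep}
    opt = _Adam(config.learning_rate)
    best_loss = np.inf
    best_params = None
    best_epoch = 0
    stall = 0
    traces: list[TrainingTrace] = []
    stopped_early = False
    for epoch in range(config.max_epochs):
        total, fit_terms, reg, grads = _loss_and_grads(params, blocks, config)
        if not np.isfinite(total):
            raise OptimizationError(
                f"non-finite objective at epoch {epoch} "
                f"(learning_rate={config.learning_rate}); reduce the learning rate"
            )
        traces.append(TrainingTrace(epoch, total, fit_terms, reg))
        if total < best_loss - config.tol * max(1.0, abs(best_loss if np.isfinite(best_loss) else total)):
            best_loss = total
            best_epoch = epoch
            best_params = {
                "U": params["U"].copy(),
                "Z": [[z.copy() for z in zl] for zl in params["Z"]],
                "H": [h.copy() for h in params["H"]],
            }
            stall = 0
        else:
            if total < best_loss:  # still the best snapshot, just a small gain
                best_loss = total
                best_epoch = epoch
                best_params = {
                    "U": params["U"].copy(),
                    "Z": [[z.copy() for z in zl] for zl in params["Z"]],
                    "H": [h.copy() for h in params["H"]],
                }
            stall += 1
            if stall >= config.patience:
                stopped_early = True
                break
        opt.t += 1
        params["U"] = opt.step("U", params["U"], grads["U"])
        for i in range(len(blocks)):
            for n in range(len(params["Z"][i])):
                params["Z"][i][n] = opt.step(("Z", i, n), params["Z"][i][n], grads["Z"][i][n])
            params["H"][i] = opt.step(("H", i), params["H"][i], grads["H"][i])
    if best_params is None:  # max_epochs == 0 cannot happen; keep init
        best_params = params
    for t in traces:
        t.best_epoch = best_epoch
        t.stopped_early = stopped_early
    model.U = best_params["U"]
    model.Z = best_params["Z"]
    model.H_deep = best_params["H"]
    model.loss_trace = [t.total_loss for t in traces]
    return model, traces, best_loss


def _perturbed(model: FactorModel, rng: np.random.Generator, scale: float = 0.3) -> FactorModel:
    """Copy of an initialized model with factor-scaled Gaussian jitter."""

    def jitter(a: np.ndarray) -> np.ndarray:
        return a + rng.normal(scale=scale * max(float(np.std(a)), 1e-3), size=a.shape)

    return FactorModel(
        U=jitter(model.U),
        Z=[[jitter(z) for z in zl] for zl in model.Z],
        H_deep=[jitter(h) for h in model.H_deep],
        config=model.config,
        block_names=list(model.block_names),
        row_ids=model.row_ids,
        col_ids=model.col_ids,
    )


def fit(
    blocks: list[DataBlock], config: ModelConfig, init: str = "auto",
    n_restarts: int = 0,
) -> tuple[FactorModel, list[TrainingTrace]]:
    """Fit the decomposition by Adam from the SVD initialization.

    ``init="auto"`` runs Adam from the two deterministic SVD starts (with
    and without the least-squares refit of U against the activated latent)
    and keeps the run with the lower final objective; the two starts
    coincide for the identity activation, in which case only one run is
    made.  ``"svd"`` / ``"svd_raw"`` force a single start.  ``n_restarts``
    adds that many perturbed copies of the raw start (jitter seeded from
    ``config.seed``) — a cheap multi-start guard against local minima;
    selection is always by the final training objective.

    Early stopping monitors the total training objective: when the best
    value seen has not improved by a relative ``tol`` for ``patience``
    consecutive epochs, training stops and the best-objective snapshot is
    restored.  Fully deterministic given the data and config.
    """
    starts: list[FactorModel] = []
    if init in ("auto", "svd"):
        starts.append(svd_initialize(blocks, config, refit_U=True))
    if init in ("auto", "svd_raw"):
        raw = svd_initialize(blocks, config, refit_U=False)
        if not (starts and np.allclose(starts[0].U, raw.U)):
            starts.append(raw)
    if not starts:
        raise ConfigurationError(f"unknown init strategy {init!r}")
    if n_restarts > 0:
        base = svd_initialize(blocks, config, refit_U=False)
        rng = np.random.default_rng(config.seed % (2**31 - 1))
        starts.extend(_perturbed(base, rng) for _ in range(n_restarts))
    best = None
    for start in starts:
        result = _adam_run(start, blocks, config)
        if best is None or result[2] < best[2]:
            best = result
    model, traces, _ = best
    return model, traces


# ---------------------------------------------------------------------------
# feature extraction


def extract_features(
    model: FactorModel,
    layer: int = 0,
    block: int | None = None,
    mode: str = "feature_matched",
) -> np.ndarray:
    """Per-sample latent features for downstream classification.

    In feature-matched mode the samples are a block's columns and the
    features are that block's layer-``layer`` latent, transposed to
    (samples x K_layer).  In sample-matched mode the samples are the shared
    rows and the features are the rows of U (the only shared per-sample
    object; ``layer`` is ignored).
    """
    if mode == "sample_matched":
        return model.U.copy()
    if mode != "feature_matched":
        raise ConfigurationError(f"unknown mode {mode!r}")
    if block is None:
        raise ConfigurationError("feature_matched mode requires a block index")
    if not 0 <= layer <= model.n_layers:
        raise IndexError(f"layer {layer} out of range [0, {model.n_layers}]")
    return layer_latents(model, block)[layer].T.copy()


# ---------------------------------------------------------------------------
# estimator


class JDSNMF(TransformerMixin, BaseEstimator):
    """Joint deep semi-NMF as a scikit-learn style transformer.

    Parameters
    ----------
    dims : tuple of int
        Strictly decreasing layer dimensions (K_0, ..., K_N); a single
        entry gives the one-layer model.
    activation : {"sigmoid", "relu", "identity"}
        Elementwise non-linearity linking consecutive layers.
    l2_lambda : float
        L2 penalty on every free factor.
    learning_rate, max_epochs, patience, tol : optimisation settings.
    mode : {"sample_matched", "feature_matched"}
        Which axis the blocks share; controls what :meth:`transform`
        returns per sample.
    layer : int
        Layer whose latent supplies per-sample features in feature-matched
        mode.
    random_state : int
        Recorded for reproducibility bookkeeping; the fit itself is
        deterministic given the data.

    Attributes
    ----------
    model_ : FactorModel
        The fitted factors (shared ``U``, junctions ``Z``, deepest
        latents ``H_deep``).
    loss_trace_ : list of float
        Objective value per epoch.
    n_iter_ : int
        Number of epochs run.

    Examples
    --------
    >>> import numpy as np
    >>> from jdsnmf import JDSNMF
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(30, 20))
    >>> est = JDSNMF(dims=(4, 3), max_epochs=200).fit([X])
    >>> est.model_.U.shape
    (30, 4)
    """

    def __init__(
        self,
        dims: tuple[int, ...] = (10, 5),
        activation: str = "sigmoid",
        l2_lambda: float = 0.0,
        learning_rate: float = 1e-3,
        max_epochs: int = 2000,
        patience: int = 50,
        tol: float = 1e-5,
        mode: str = "feature_matched",
        layer: int = 0,
        random_state: int = 0,
    ):
        self.dims = dims
        self.activation = activation
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.mode = mode
        self.layer = layer
        self.random_state = random_state

    def _as_blocks(self, X) -> list[DataBlock]:
        if isinstance(X, DataBlock):
            return [X]
        if isinstance(X, np.ndarray):
            return [DataBlock.from_array(X)]
        blocks = []
        for i, x in enumerate(X):
            blocks.append(x if isinstance(x, DataBlock) else DataBlock.from_array(x, name=f"block{i}"))
        return blocks

    def _config(self) -> ModelConfig:
        return ModelConfig(
            dims=tuple(self.dims),
            activation=self.activation,
            l2_lambda=self.l2_lambda,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Fit the joint decomposition.

        ``X`` is a single matrix/DataBlock or a list of row-aligned ones.
        """
        blocks = self._as_blocks(X)
        self.model_, self.traces_ = fit(blocks, self._config())
        self.loss_trace_ = self.model_.loss_trace
        self.n_iter_ = len(self.loss_trace_)
        self.n_blocks_ = len(blocks)
        return self

    def fit_transform(self, X, y=None):
        """Fit and return per-sample latent features (transductive)."""
        self.fit(X)
        return self.sample_features()

    def transform(self, X=None):
        """Per-sample features of the fitted data.

        The decomposition is transductive — like spectral embeddings there
        is no out-of-sample map — so ``X`` must be None or the training
        input is simply re-reported.
        """
        if not hasattr(self, "model_"):
            raise ConfigurationError("JDSNMF instance is not fitted yet")
        return self.sample_features()

    def sample_features(self, layer: int | None = None, block: int | None = None) -> np.ndarray:
        """Features per sample; see :func:`extract_features`."""
        layer = self.layer if layer is None else layer
        if self.mode == "sample_matched":
            return extract_features(self.model_, layer, None, "sample_matched")
        if block is not None:
            return extract_features(self.model_, layer, block, "feature_matched")
        feats = [
            extract_features(self.model_, layer, i, "feature_matched")
            for i in range(self.model_.n_blocks)
        ]
        return np.vstack(feats) if len(feats) > 1 else feats[0]

    def reconstruct(self, block: int = 0) -> np.ndarray:
        return reconstruct_block(self.model_, block)

    def objective_(self, X) -> float:
        total, _, _ = objective(self.model_, self._as_blocks(X))
        return total
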