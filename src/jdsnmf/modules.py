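"""Latent-module construction by z-score thresholding.

Each first-layer latent dimension k defines one *module*.  A block's
samples join module k when their value in row k of that block's first-layer
sample latent exceeds mu + 1.6449 sigma (the upper 5% of a normal).
Features join with a sign: positive when their value in column k of the
shared feature latent U exceeds mu + 2.5758 sigma, negative below
mu - 2.5758 sigma (1% two-sided).  Statistics are computed per module
(per latent dimension) with the population sigma; membership is not
exclusive — an entity may appear in several modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import DataBlock, FactorModel
from .factorization import layer_latents

__all__ = [
    "SAMPLE_Z_CUTOFF",
    "FEATURE_Z_CUTOFF",
    "Module",
    "sample_membership",
    "feature_membership",
    "build_modules",
]

# standard normal quantiles: upper 5% and two-sided 1%
SAMPLE_Z_CUTOFF = 1.6449
FEATURE_Z_CUTOFF = 2.5758


@dataclass
class Module:
    """Samples (per block) and signed features assigned to one latent dim."""

    index: int
    samples_per_block: dict[str, list[str]] = field(default_factory=dict)
    positive_features: list[str] = field(default_factory=list)
    negative_features: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        n = len(self.positive_features) + len(self.negative_features)
        return n + sum(len(v) for v in self.samples_per_block.values())


def _stats(values: np.ndarray, scope: str, matrix: np.ndarray) -> tuple[float, float]:
    if scope == "per_module":
        return float(values.mean()), float(values.std())  # ddof=0
    if scope == "global":
        return float(matrix.mean()), float(matrix.std())
    raise ValueError(f"unknown statistics scope {scope!r}")


def sample_membership(
    H0: np.ndarray,
    k: int,
    sample_ids: list[str] | None = None,
    cutoff: float = SAMPLE_Z_CUTOFF,
    scope: str = "per_module",
) -> list[str]:
    """Samples whose value in latent row ``k`` exceeds mu + 1.6449 sigma."""
    H0 = np.asarray(H0, dtype=float)
    row = H0[k]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(row.size)]
    mu, sd = _stats(row, scope, H0)
    if sd == 0.0:
        warnings.warn(f"module {k}: constant sample latent row, empty selection", stacklevel=2)
        return []
    thr = mu + cutoff * sd
    return [sid for sid, v in zip(sample_ids, row) if v > thr]


def feature_membership(
    U: np.ndarray,
    k: int,
    feature_ids: list[str] | None = None,
    cutoff: float = FEATURE_Z_CUTOFF,
    scope: str = "per_module",
) -> tuple[list[str], list[str]]:
    """(positive, negative) features for module ``k`` from column ``k`` of U."""
    U = np.asarray(U, dtype=float)
    col = U[:, k]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(col.size)]
    mu, sd = _stats(col, scope, U)
    if sd == 0.0:
        warnings.warn(f"module {k}: constant feature latent column, empty selection", stacklevel=2)
        return [], []
    hi, lo = mu + cutoff * sd, mu - cutoff * sd
    pos = [fid for fid, v in zip(feature_ids, col) if v > hi]
    neg = [fid for fid, v in zip(feature_ids, col) if v < lo]
    return pos, neg


def build_modules(
    model: FactorModel,
    blocks: list[DataBlock] | None = None,
    scope: str = "per_module",
) -> list[Module]:
    """One module per first-layer dimension, from U and each block's H^0.

    Sample thresholds are computed per block per module; empty modules are
    kept so the list always has K_0 entries.
    """
    k0 = model.config.dims[0]
    feature_ids = model.row_ids or [f"f{j}" for j in range(model.U.shape[0])]
    h0_per_block = [layer_latents(model, i)[0] for i in range(model.n_blocks)]
    col_ids = model.col_ids or [
        [f"s{j}" for j in range(h.shape[1])] for h in h0_per_block
    ]
    modules: list[Module] = []
    for k in range(k0):
        mod = Module(index=k)
        col = model.U[:, k]
        mu, sd = _stats(col, scope, model.U)
        mod.thresholds["feature_positive"] = mu + FEATURE_Z_CUTOFF * sd
        mod.thresholds["feature_negative"] = mu - FEATURE_Z_CUTOFF * sd
        mod.positive_features, mod.negative_features = feature_membership(
            model.U, k, feature_ids, scope=scope
        )
        for i, name in enumerate(model.block_names):
            row = h0_per_block[i][k]
            mu_s, sd_s = _stats(row, scope, h0_per_block[i])
            mod.thresholds[f"sample_{name}"] = mu_s + SAMPLE_Z_CUTOFF * sd_s
            mod.samples_per_block[name] = sample_membership(
                h0_per_block[i], k, col_ids[i], scope=scope
            )
        modules.append(mod)
    return modules
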