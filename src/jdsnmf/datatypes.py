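"""Core containers: data blocks, model configuration, fitted factor models.

A *block* is one numeric data matrix (e.g. gene expression, DNA methylation)
oriented so that the matched axis — the axis shared by every block in the
analysis — is always the rows.  In a sample-matched analysis the rows are
samples; in a feature-matched analysis the rows are features (e.g. genes
common to both platforms) and the columns are each block's own samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ShapeError

__all__ = ["DataBlock", "ModelConfig", "FactorModel", "TrainingTrace"]

_ACTIVATIONS = ("sigmoid", "relu", "identity")


@dataclass
class DataBlock:
    """One data matrix with identifiers on both axes.

    Parameters
    ----------
    name : str
        Block label (e.g. ``"GE"``, ``"DM"``).
    values : ndarray of shape (C, M)
        Dense numeric matrix, matched axis on the rows.
    row_ids, col_ids : list of str
        Entity identifiers; ``row_ids`` is the matched axis and must be
        identical (same order) across all blocks of one analysis.
    orientation : {"as_is", "transposed"}
        Whether the loader transposed the raw file to put the matched axis
        on the rows.
    """

    name: str
    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation: str = "as_is"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"block {self.name!r}: values must be 2-D")
        c, m = self.values.shape
        if c < 2 or m < 2:
            raise ShapeError(f"block {self.name!r}: need at least 2x2, got {c}x{m}")
        if len(self.row_ids) != c or len(self.col_ids) != m:
            raise ShapeError(
                f"block {self.name!r}: id lists ({len(self.row_ids)}, "
                f"{len(self.col_ids)}) do not match shape {c}x{m}"
            )
        if not np.isfinite(self.values).all():
            raise ShapeError(f"block {self.name!r}: contains missing/non-finite values")
        if self.orientation not in ("as_is", "transposed"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if np.ptp(self.values) == 0.0:
            warnings.warn(f"block {self.name!r} has zero variance", stacklevel=2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_array(cls, values, name: str = "block") -> "DataBlock":
        """Wrap a bare array, generating positional identifiers."""
        values = np.asarray(values, dtype=float)
        rows = [f"r{i}" for i in range(values.shape[0])]
        cols = [f"c{j}" for j in range(values.shape[1])]
        return cls(name=name, values=values, row_ids=rows, col_ids=cols)


@dataclass
class ModelConfig:
    """Hyperparameters of the joint deep semi-NMF decomposition.

    ``dims`` lists the reduced dimension of every layer, first layer first
    (K_0 > K_1 > ... > K_N, so ``n_layers = len(dims) - 1``).  ``l2_lambda``
    is the L2 penalty applied to every free factor.
    """

    dims: tuple[int, ...]
    activation: str = "sigmoid"
    l2_lambda: float = 0.0
    learning_rate: float = 1e-3
    max_epochs: int = 2000
    patience: int = 50
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(k) for k in self.dims)
        if len(self.dims) < 2:
            raise ConfigurationError(
                f"dims needs at least (K_0, K_1) — one junction layer; got {self.dims}"
            )
        if any(k < 1 for k in self.dims):
            raise ConfigurationError(f"dims must be positive integers, got {self.dims}")
        if any(a <= b for a, b in zip(self.dims, self.dims[1:])):
            raise ConfigurationError(f"dims must be strictly decreasing, got {self.dims}")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"unsupported activation {self.activation!r}; choose from {_ACTIVATIONS}"
            )
        if self.l2_lambda < 0:
            raise ConfigurationError("l2_lambda must be non-negative")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_epochs < 1 or self.patience < 1:
            raise ConfigurationError("max_epochs and patience must be positive")
        if self.tol < 0:
            raise ConfigurationError("tol must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def validate_against(self, blocks: list[DataBlock]) -> None:
        c = blocks[0].shape[0]
        m_min = min(b.shape[1] for b in blocks)
        if self.dims[0] >= min(c, m_min):
            raise ConfigurationError(
                f"first-layer dimension K0={self.dims[0]} must be smaller than "
                f"min(C, min_i M_i) = {min(c, m_min)}"
            )

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "activation": self.activation,
            "l2_lambda": self.l2_lambda,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "tol": self.tol,
            "seed": self.seed,
        }


@dataclass
class TrainingTrace:
    """Per-epoch record of the decomposed objective."""

    epoch: int
    total_loss: float
    per_block_loss: list[float]
    reg_loss: float
    stopped_early: bool = False
    best_epoch: int = 0


@dataclass
class FactorModel:
    """The fitted decomposition.

    ``U`` (C x K0) is the shared latent matrix on the matched axis and is
    unconstrained in sign, as are the junction matrices ``Z[i][n-1]``
    (K_{n-1} x K_n, n = 1..N) and each block's deepest free latent
    ``H_deep[i]`` (K_N x M_i).  The intermediate layer latents
    H^{n-1} = g(Z^n H^n) are derived, never stored as free parameters, and
    are non-negative by construction of the activation g.
    """

    U: np.ndarray
    Z: list[list[np.ndarray]]
    H_deep: list[np.ndarray]
    config: ModelConfig
    block_names: list[str] = field(default_factory=list)
    row_ids: list[str] | None = None
    col_ids: list[list[str]] | None = None
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.block_names:
            self.block_names = [f"block{i}" for i in range(len(self.H_deep))]

    @property
    def n_blocks(self) -> int:
        return len(self.H_deep)

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def check_shapes(self) -> None:
        dims = self.config.dims
        k0 = dims[0]
        if self.U.shape[1] != k0:
            raise ShapeError(f"U has {self.U.shape[1]} columns, expected K0={k0}")
        for i in range(self.n_blocks):
            if len(self.Z[i]) != self.n_layers:
                raise ShapeError(
                    f"block {i}: expected {self.n_layers} junction matrices, got {len(self.Z[i])}"
                )
            for n, z in enumerate(self.Z[i], start=1):
                want = (dims[n - 1], dims[n])
                if z.shape != want:
                    raise ShapeError(f"block {i}, layer {n}: Z has shape {z.shape}, expected {want}")
            if self.H_deep[i].shape[0] != dims[-1]:
                raise ShapeError(
                    f"block {i}: deepest latent has {self.H_deep[i].shape[0]} rows, "
                    f"expected K_N={dims[-1]}"
                )
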