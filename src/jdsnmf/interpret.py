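"""Module-level interpretation.

Three tools, all operating on the per-sample module features (a samples x
modules matrix of latent values):

* local-surrogate importance — a LIME-style explanation that perturbs
  instances, weights perturbations by an exponential distance kernel and
  fits a ridge surrogate to the black-box class probabilities, summing
  absolute surrogate weights per module over instances (and classifiers);
* an age-association regression per module — ordinary least squares of the
  module's sample latent value on age, sex and diagnosis plus the latent
  matrix's principal components that are *not* associated with age;
* Fisher's exact test for overlap between a module's gene list and a
  reference gene set within a stated universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Ridge

from .exceptions import ConfigurationError, DegenerateInputError, DegenerateTestError

__all__ = [
    "ImportanceReport",
    "AgeRegressionResult",
    "local_surrogate_importance",
    "rf_module_importance",
    "age_regression",
    "overlap_fisher",
    "importance_vs_pathway_regression",
    "read_gmt",
]


@dataclass
class ImportanceReport:
    """Summed local-surrogate weights per module, with ranks (0 = top)."""

    weights: np.ndarray
    per_instance: np.ndarray
    rank: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.weights)[::-1]
        self.rank = np.empty_like(order)
        self.rank[order] = np.arange(order.size)

    @property
    def top_module(self) -> int:
        return int(np.argmax(self.weights))


def local_surrogate_importance(
    predict_fn,
    X: np.ndarray,
    instances: np.ndarray | None = None,
    n_perturbations: int = 1000,
    kernel_width: float | None = None,
    alpha: float = 1.0,
    seed: int = 0,
) -> ImportanceReport:
    """Perturbation-based local linear surrogate importance.

    For each instance, ``n_perturbations`` samples are drawn around it
    (Gaussian, per-feature scale = the feature's std over X), weighted by
    exp(-d^2 / kernel_width^2) on standardized distance, and a ridge
    surrogate is fit to ``predict_fn``'s positive-class probability.  The
    report sums absolute surrogate coefficients over instances.
    """
    X = np.asarray(X, dtype=float)
    if instances is None:
        instances = np.arange(X.shape[0])
    d = X.shape[1]
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    scales = X.std(axis=0)
    live = scales > 0
    safe_scales = np.where(live, scales, 1.0)
    rng = np.random.default_rng(seed)
    per_instance = np.zeros((len(instances), d))
    for row, idx in enumerate(instances):
        x0 = X[idx]
        pert = x0 + rng.normal(size=(n_perturbations, d)) * safe_scales * live
        probs = np.asarray(predict_fn(pert), dtype=float)
        if probs.ndim == 2:
            probs = probs[:, -1]
        if np.ptp(probs) == 0.0:
            warnings.warn("constant predictions around instance; zero surrogate weights",
                          stacklevel=2)
            continue
        z = (pert - x0) / safe_scales
        dist = np.linalg.norm(z, axis=1)
        w = np.exp(-(dist**2) / kernel_width**2)
        surrogate = Ridge(alpha=alpha)
        surrogate.fit(z, probs, sample_weight=w)
        per_instance[row] = np.abs(surrogate.coef_)
    return ImportanceReport(weights=per_instance.sum(axis=0), per_instance=per_instance)


def rf_module_importance(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, n_estimators: int = 500
) -> np.ndarray:
    """Normalized impurity importances of a random forest (sum to 1)."""
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(features, labels)
    imp = rf.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp


@dataclass
class AgeRegressionResult:
    module: int
    gamma: float  # age coefficient
    p_value: float
    sex_coef: float | None
    diagnosis_coef: float | None
    n_pcs_used: int


def age_regression(
    sample_latent: np.ndarray,
    covariates: pd.DataFrame,
    pc_alpha: float = 0.05,
    max_pcs: int = 10,
) -> list[AgeRegressionResult]:
    """Per-module OLS of latent value on age, sex, diagnosis and PCs.

    ``sample_latent`` is samples x modules; ``covariates`` must carry
    columns ``age``, ``sex``, ``diagnosis`` row-aligned with the samples.
    Principal components of the latent matrix whose Pearson correlation
    with age has p >= ``pc_alpha`` (i.e. PCs not related to age) enter as
    nuisance covariates; only the top ``max_pcs`` components are
    considered so the design stays well-conditioned.  Constant covariates
    are dropped with a warning.
    """
    Y = np.asarray(sample_latent, dtype=float)
    if Y.shape[0] != len(covariates):
        raise ConfigurationError("covariates not aligned with sample latent rows")
    for col in ("age", "sex", "diagnosis"):
        if col not in covariates.columns:
            raise ConfigurationError(f"covariates missing column {col!r}")
        if covariates[col].isna().any():
            raise ConfigurationError(f"missing values in covariate {col!r}")
    age = covariates["age"].to_numpy(dtype=float)
    n_comp = min(max_pcs, min(Y.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=0).fit_transform(Y) if n_comp >= 1 else np.empty((Y.shape[0], 0))
    keep = []
    for k in range(pcs.shape[1]):
        if np.std(pcs[:, k]) == 0:
            continue
        _, p = stats.pearsonr(pcs[:, k], age)
        if p >= pc_alpha:
            keep.append(k)
    pcs = pcs[:, keep]

    cols = {"age": age}
    for col in ("sex", "diagnosis"):
        v = covariates[col]
        v = v.astype("category").cat.codes.to_numpy(dtype=float) if v.dtype == object else v.to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"covariate {col!r} is constant; dropped", stacklevel=2)
        else:
            cols[col] = v
    design = pd.DataFrame(cols)
    for k in range(pcs.shape[1]):
        design[f"pc{k}"] = pcs[:, k]
    exog = sm.add_constant(design, has_constant="add")
    results = []
    for j in range(Y.shape[1]):
        fit = sm.OLS(Y[:, j], exog).fit()
        results.append(
            AgeRegressionResult(
                module=j,
                gamma=float(fit.params["age"]),
                p_value=float(fit.pvalues["age"]),
                sex_coef=float(fit.params["sex"]) if "sex" in fit.params else None,
                diagnosis_coef=float(fit.params["diagnosis"]) if "diagnosis" in fit.params else None,
                n_pcs_used=pcs.shape[1],
            )
        )
    return results


def overlap_fisher(
    module_genes, reference_genes, universe_genes
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 overlap table."""
    universe = set(universe_genes)
    if not universe:
        raise DegenerateInputError("empty gene universe")
    mod = set(module_genes) & universe
    ref = set(reference_genes) & universe
    a = len(mod & ref)
    b = len(mod - ref)
    c = len(ref - mod)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def importance_vs_pathway_regression(importance, counts) -> tuple[float, float, float]:
    """Pearson r, two-sided p and OLS slope of counts on importance."""
    x = np.asarray(importance, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateTestError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return float(r), float(p), slope


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
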