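"""Downstream-classification evaluation protocol.

Latent features from each factorization are scored by pluggable
classifiers with fixed settings (linear SVM, random forest, small
feed-forward net); performance is the area under the ROC curve on held-out
samples, and paired AUC vectors from two methods are compared with the
two-sided Wilcoxon signed-rank test.  Hyperparameters of the factorizations
are selected on validation AUC only — test labels never enter selection.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .exceptions import ConfigurationError, DegenerateTestError, SplitError
from .factorization import JDSNMF
from .nmf import MultiplicativeNMF
from .simulate import MultiViewSample, SimulationDesign, simulate_multiview

__all__ = [
    "EvalResult",
    "default_classifiers",
    "stratified_splits",
    "evaluate_features",
    "run_benchmark",
    "wilcoxon_compare",
    "t_filter_features",
]


@dataclass
class EvalResult:
    method: str
    replicate: int
    classifier: str
    auc: float
    hyperparameters: dict

    def to_row(self) -> dict:
        row = asdict(self)
        row["hyperparameters"] = str(row["hyperparameters"])
        return row


def default_classifiers(seed: int = 0) -> dict:
    """Fixed classifier battery: linear SVM, random forest, small MLP.

    The forest uses 500 trees; the net is three fully connected layers with
    L2 regularization and early stopping.
    """
    return {
        "svm": make_pipeline(StandardScaler(), LinearSVC(C=1.0, random_state=seed)),
        "rf": RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1),
        "dnn": make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(64, 32, 16),
                alpha=1e-3,
                early_stopping=True,
                max_iter=500,
                random_state=seed,
            ),
        ),
    }


def stratified_splits(
    labels: np.ndarray,
    scheme: str = "kfold",
    n_splits: int = 5,
    ratios: tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
):
    """Label-stratified index partitions.

    ``scheme="kfold"`` returns a list of (train_idx, test_idx) pairs whose
    test folds are disjoint and exhaustive; ``scheme="train_valid_test"``
    returns one (train, valid, test) triple with sizes in ``ratios``
    proportion.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise SplitError("need at least two classes to stratify")
    if scheme == "kfold":
        if counts.min() < n_splits:
            raise SplitError(
                f"smallest class has {counts.min()} members, fewer than {n_splits} folds"
            )
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros_like(labels), labels)]
    if scheme == "train_valid_test":
        total = sum(ratios)
        if counts.min() < total:
            raise SplitError("smallest class too small for the requested ratios")
        rng = np.random.default_rng(seed)
        parts: list[list[int]] = [[], [], []]
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            n = idx.size
            n_tr = int(round(n * ratios[0] / total))
            n_va = int(round(n * ratios[1] / total))
            parts[0].extend(idx[:n_tr])
            parts[1].extend(idx[n_tr : n_tr + n_va])
            parts[2].extend(idx[n_tr + n_va :])
        return tuple(np.sort(np.array(p, dtype=int)) for p in parts)
    raise ConfigurationError(f"unknown split scheme {scheme!r}")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        return proba[:, 1] if proba.shape[1] == 2 else proba
    return clf.decision_function(X)


def evaluate_features(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    classifiers: dict | None = None,
    method: str = "features",
    replicate: int = 0,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> list[EvalResult]:
    """Fit each classifier on the training split and report test AUC.

    Binary AUC uses the positive-class score; multiclass AUC is the
    one-vs-rest macro average.
    """
    if np.unique(y_test).size < 2:
        raise DegenerateTestError("test split contains a single class; AUC undefined")
    classifiers = classifiers or default_classifiers(seed)
    results = []
    for name, proto in classifiers.items():
        clf = clone(proto)
        clf.fit(X_train, y_train)
        scores = _scores(clf, X_test)
        if scores.ndim == 1:
            auc = roc_auc_score(y_test, scores)
        else:
            auc = roc_auc_score(y_test, scores, multi_class="ovr", average="macro")
        results.append(
            EvalResult(method, replicate, name, float(auc), hyperparameters or {})
        )
    return results


def t_filter_features(
    X_train, y_train, X_all, n_keep: int = 50
) -> np.ndarray:
    """Univariate t-statistic filter baseline for synthetic benchmarks.

    Simple per-feature two-sample t ranking on the training split.  This is
    a generic stand-in baseline, not part of the published comparison
    (which used limma moderated statistics on real microarray data).
    """
    X_train = np.asarray(X_train, dtype=float)
    g0, g1 = X_train[y_train == 0], X_train[y_train == 1]
    num = g1.mean(axis=0) - g0.mean(axis=0)
    den = np.sqrt(g1.var(axis=0, ddof=1) / len(g1) + g0.var(axis=0, ddof=1) / len(g0))
    t = np.abs(num / np.maximum(den, 1e-12))
    keep = np.argsort(t)[::-1][:n_keep]
    return np.asarray(X_all)[:, np.sort(keep)]


# ---------------------------------------------------------------------------
# benchmark harness


def _shift_nonneg(X: np.ndarray) -> np.ndarray:
    return X - X.min(axis=0, keepdims=True)


def _method_features(method: str, data: MultiViewSample, params: dict, seed: int) -> np.ndarray:
    """Transductive per-sample features for one factorization method."""
    xcat = np.concatenate(data.views, axis=1)
    if method == "nmf":
        est = MultiplicativeNMF(
            n_components=params.get("k", 10),
            max_iter=params.get("max_iter", 200),
            random_state=seed,
        )
        return est.fit_transform(_shift_nonneg(xcat))
    common = dict(
        activation=params.get("activation", "sigmoid"),
        l2_lambda=params.get("l2_lambda", 0.01),
        learning_rate=params.get("learning_rate", 0.01),
        max_epochs=params.get("max_epochs", 300),
        patience=params.get("patience", 30),
        mode="sample_matched",
        random_state=seed,
    )
    if method == "deep_semi_nmf":
        est = JDSNMF(dims=params.get("dims", (20, 10)), **common)
        return est.fit_transform([xcat])
    if method == "jdsnmf":
        est = JDSNMF(dims=params.get("dims", (20, 10)), **common)
        return est.fit_transform(list(data.views))
    raise ConfigurationError(f"unknown method {method!r}")


def run_benchmark(
    design: SimulationDesign,
    methods: tuple[str, ...] = ("nmf", "deep_semi_nmf", "jdsnmf"),
    grid: dict | None = None,
    replicates: int = 5,
    seed: int = 0,
    classifiers: dict | None = None,
) -> pd.DataFrame:
    """Repeat the simulation benchmark and tabulate test AUCs.

    Per replicate: generate a fresh multi-view dataset, fit every method
    for every hyperparameter set, pick the set with the best validation AUC
    (linear SVM), then report the test AUC of the chosen set for each
    classifier in the battery (default: linear SVM only, matching the
    simulation protocol).
    """
    grid = grid or {
        "nmf": [{"k": 10}, {"k": 20}],
        "deep_semi_nmf": [{"dims": (20, 10)}, {"dims": (30, 15)}],
        "jdsnmf": [{"dims": (20, 10)}, {"dims": (30, 15)}],
    }
    for m in methods:
        if not grid.get(m):
            raise ConfigurationError(f"empty hyperparameter grid for method {m!r}")
    classifiers = classifiers or {"svm": default_classifiers(seed)["svm"]}
    selector = default_classifiers(seed)["svm"]
    rows: list[EvalResult] = []
    for rep in range(replicates):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        data = simulate_multiview(design, seed=rep_seed)
        y = data.labels
        tr, va, te = data.train_idx, data.valid_idx, data.test_idx
        for method in methods:
            best_auc, best_params, best_feats = -np.inf, None, None
            for params in grid[method]:
                feats = _method_features(method, data, params, rep_seed)
                sel = clone(selector)
                sel.fit(feats[tr], y[tr])
                val_auc = roc_auc_score(y[va], _scores(sel, feats[va]))
                if val_auc > best_auc:
                    best_auc, best_params, best_feats = val_auc, params, feats
            rows.extend(
                evaluate_features(
                    best_feats[tr], y[tr], best_feats[te], y[te],
                    classifiers=classifiers, method=method, replicate=rep,
                    hyperparameters=best_params, seed=rep_seed,
                )
            )
    return pd.DataFrame([r.to_row() for r in rows])


def wilcoxon_compare(aucs_a, aucs_b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on AUC vectors."""
    a, b = np.asarray(aucs_a, dtype=float), np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ConfigurationError("need equal-length paired vectors of length >= 5")
    if np.all(a == b):
        raise DegenerateTestError("all paired differences are zero")
    stat, p = wilcoxon(a, b, alternative="two-sided")
    return float(stat), float(p)
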