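"""Connectome-based prediction (NBS-Predict style).

Repeated stratified k-fold cross-validation in which edge selection — a
per-edge two-sample t test thresholded at ``p_thresh`` followed by taking the
largest connected component of the surviving edges — happens inside each
training fold only.  Linear classifiers (logistic regression, linear SVM,
LDA) are trained on the selected edge values after train-fold
standardization; fold metrics are aggregated and every edge's selection
frequency across folds forms the weighted network.  Statistical significance
of the observed mean AUC comes from rerunning the whole procedure under label
permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .nbs import _two_sample_t, stack_matrices
from .spectral import ConnectivityMatrix
from .stats import rank_auc

__all__ = ["NBSPredictResult", "nbs_predict_run", "permutation_significance", "weighted_network"]

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("logistic", "linear_svm", "lda")


def _make_model(name: str):
    # Standard linear models, default regularization; hyperparameters are
    # not tuned anywhere in the pipeline.
    if name == "logistic":
        return LogisticRegression(C=1.0, max_iter=1000)
    if name == "linear_svm":
        return LinearSVC(C=1.0)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown model {name!r}")


@dataclass
class NBSPredictResult:
    fold_metrics: pd.DataFrame  # repeat, fold, model, auc, accuracy, sensitivity, specificity, n_edges
    selection_counts: np.ndarray  # per-edge count of (repeat, fold) selections
    n_folds_total: int
    channels: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    best_model: str = ""
    labels_order: tuple[str, str] = ("ASD", "TD")  # (positive, negative)
    params: dict = field(default_factory=dict)
    null_auc: np.ndarray | None = None
    null_mean_auc: float = np.nan
    p_value: float = np.nan

    @property
    def selection_frequency(self) -> np.ndarray:
        return self.selection_counts / self.n_folds_total

    def mean_metrics(self) -> pd.DataFrame:
        return (self.fold_metrics
                .groupby("model")[["auc", "accuracy", "sensitivity", "specificity"]]
                .mean())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics.loc[
            self.fold_metrics["model"] == self.best_model, "auc"].mean())


def _select_edges(
    X_train: np.ndarray, y_train: np.ndarray, p_thresh: float,
    pair_i: np.ndarray, pair_j: np.ndarray, component: bool = True,
) -> np.ndarray:
    """Training-fold edge selection: t-test threshold, then largest component."""
    t, df, _ = _two_sample_t(X_train[y_train == 1], X_train[y_train == 0])
    p = 2.0 * sps.t.sf(np.abs(t), df)
    supra = np.flatnonzero(p < p_thresh)
    if supra.size == 0 or not component:
        return supra
    # largest connected component of the suprathreshold graph
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in supra:
        i, j = int(pair_i[e]), int(pair_j[e])
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(int(pair_i[e])) for e in supra])
    best_root = None
    best_count = -1
    for r in set(roots.tolist()):
        c = int((roots == r).sum())
        if c > best_count:
            best_count, best_root = c, r
    return supra[roots == best_root]


def _fold_scores(model, X_tr, y_tr, X_te) -> np.ndarray:
    try:
        model.fit(X_tr, y_tr)
        return model.decision_function(X_te)
    except (np.linalg.LinAlgError, IndexError, ValueError):
        # degenerate within-class covariance (e.g. a zero-within-variance
        # perfectly separating edge breaks LDA's svd): fall back to the
        # nearest-centroid discriminant, LDA's limit for vanishing scatter
        mu1 = X_tr[y_tr == 1].mean(axis=0)
        mu0 = X_tr[y_tr == 0].mean(axis=0)
        w = mu1 - mu0
        b = -0.5 * (mu1 + mu0) @ w
        return X_te @ w + b


def _run_cv(
    X: np.ndarray, y: np.ndarray, k: int, repeats: int, p_thresh: float,
    models: tuple[str, ...], seed: int, pair_i: np.ndarray, pair_j: np.ndarray,
    component: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    n_edges = X.shape[1]
    counts = np.zeros(n_edges)
    rows = []
    n_folds = 0
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + rep) % 2**31)
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            n_folds += 1
            sel = _select_edges(X[tr], y[tr], p_thresh, pair_i, pair_j, component)
            counts[sel] += 1
            if sel.size == 0:
                logger.info("repeat %d fold %d: no suprathreshold edges, scoring at chance", rep, fold)
                for name in models:
                    rows.append((rep, fold, name, 0.5, 0.5, 0.5, 0.5, 0))
                continue
            # standardization is fit on the training fold only
            mu = X[tr][:, sel].mean(axis=0)
            sd = X[tr][:, sel].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X_tr = (X[tr][:, sel] - mu) / sd
            X_te = (X[te][:, sel] - mu) / sd
            for name in models:
                scores = _fold_scores(_make_model(name), X_tr, y[tr], X_te)
                auc = rank_auc(scores, y[te])
                pred = (scores > 0).astype(int)
                acc = float((pred == y[te]).mean())
                pos, neg = y[te] == 1, y[te] == 0
                sens = float((pred[pos] == 1).mean()) if pos.any() else np.nan
                spec = float((pred[neg] == 0).mean()) if neg.any() else np.nan
                rows.append((rep, fold, name, auc, acc, sens, spec, int(sel.size)))
    metrics = pd.DataFrame(
        rows, columns=["repeat", "fold", "model", "auc", "accuracy",
                       "sensitivity", "specificity", "n_edges"])
    return metrics, counts, n_folds


def nbs_predict_run(
    matrices: list[ConnectivityMatrix],
    groups: list[str],
    k: int = 5,
    repeats: int = 10,
    p_thresh: float = 0.01,
    models: tuple[str, ...] = DEFAULT_MODELS,
    seed: int = 0,
    positive_class: str = "ASD",
    component: bool = True,
) -> NBSPredictResult:
    """Repeated stratified k-fold prediction with fold-internal edge selection.

    ``groups`` gives one class label per matrix; ``positive_class`` is coded 1.
    The best model is the one with the highest mean test AUC.
    """
    X, channels, edges = stack_matrices(matrices)
    y = np.asarray([1 if g == positive_class else 0 for g in groups])
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ValueError(f"need >= k={k} subjects per class for stratified {k}-fold CV")
    pair_i, pair_j = np.triu_indices(len(channels), k=1)
    metrics, counts, n_folds = _run_cv(
        X, y, k, repeats, p_thresh, tuple(models), seed, pair_i, pair_j, component)
    mean_auc = metrics.groupby("model")["auc"].mean()
    best = str(mean_auc.idxmax())
    neg = next(g for g in dict.fromkeys(groups) if g != positive_class)
    return NBSPredictResult(
        fold_metrics=metrics,
        selection_counts=counts,
        n_folds_total=n_folds,
        channels=channels,
        edges=edges,
        best_model=best,
        labels_order=(positive_class, neg),
        params=dict(k=k, repeats=repeats, p_thresh=p_thresh,
                    models=list(models), seed=seed),
    )


def permutation_significance(
    matrices: list[ConnectivityMatrix],
    groups: list[str],
    result: NBSPredictResult,
    n_perm: int = 5000,
    seed: int = 0,
    repeats: int = 1,
) -> NBSPredictResult:
    """Label-permutation null for the observed mean AUC of the best model.

    The full CV procedure is rerun per permutation (``repeats`` may be
    reduced relative to the observed run to keep cost manageable);
    p = (1 + #{null mean AUC >= observed}) / (n_perm + 1).
    """
    if n_perm < 50:
        logger.warning("n_perm=%d is very small for a permutation p-value", n_perm)
    X, channels, _ = stack_matrices(matrices)
    positive = result.labels_order[0]
    y = np.asarray([1 if g == positive else 0 for g in groups])
    pair_i, pair_j = np.triu_indices(len(channels), k=1)
    k = result.params["k"]
    p_thresh = result.params["p_thresh"]
    model = (result.best_model,)
    rng = np.random.default_rng(seed)
    observed = result.mean_auc
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        m, _, _ = _run_cv(X, y_perm, k, repeats, p_thresh, model,
                          int(rng.integers(2**31)), pair_i, pair_j)
        null[b] = m["auc"].mean()
    result.null_auc = null
    result.null_mean_auc = float(null.mean())
    result.p_value = float((1.0 + (null >= observed).sum()) / (n_perm + 1.0))
    return result


def weighted_network(result: NBSPredictResult, top_fraction: float | None = None) -> pd.DataFrame:
    """Selection-frequency adjacency as a labeled symmetric DataFrame.

    ``top_fraction`` keeps only the strongest q-fraction of nonzero edges
    (for display); None keeps everything.
    """
    freq = result.selection_frequency.copy()
    if top_fraction is not None:
        nz = freq[freq > 0]
        if nz.size:
            cutoff = np.quantile(nz, 1.0 - top_fraction)
            freq = np.where(freq >= cutoff, freq, 0.0)
    n = len(result.channels)
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat[iu] = freq
    mat += mat.T
    return pd.DataFrame(mat, index=result.channels, columns=result.channels)
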