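"""Multicollinearity-aware feature importance.

Feature clustering uses average-linkage hierarchical clustering on the
distance 1 - |Spearman rho|; one representative is kept per cluster before
permutation importances are computed, and ranking stability is assessed over
bootstrap resamples of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from . import model_zoo
from .model_zoo import ModelConfig


@dataclass
class FeatureClustering:
    threshold: float
    labels: np.ndarray  # cluster id per (kept) feature
    representatives: list[int]  # one feature index per cluster
    feature_indices: list[int]  # indices into the original matrix (constants dropped)
    linkage: np.ndarray
    dropped_constant: list[int]

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for feat, lab in zip(self.feature_indices, self.labels):
            out.setdefault(int(lab), []).append(feat)
        return out


def spearman_cluster(X: np.ndarray, threshold: float = 0.3) -> FeatureClustering:
    """Cluster features on 1 - |Spearman rho| with average linkage.

    Flat clusters are cut at ``threshold``; the representative of each
    cluster is its member with the highest mean |rho| to the rest of the
    cluster.  Constant columns are flagged and excluded.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 features")
    const = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    keep = [j for j in range(X.shape[1]) if j not in const]
    if const:
        warnings.warn(f"excluding constant columns: {const}", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant features")
    sub = X[:, keep]
    rho = spearmanr(sub).correlation
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - np.abs(rho)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")

    representatives = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 1:
            rep_local = members[0]
        else:
            block = np.abs(rho[np.ix_(members, members)])
            mean_rho = (block.sum(axis=1) - 1.0) / (members.size - 1)
            rep_local = members[int(np.argmax(mean_rho))]
        representatives.append(keep[rep_local])
    return FeatureClustering(
        threshold=threshold,
        labels=labels,
        representatives=sorted(representatives),
        feature_indices=keep,
        linkage=Z,
        dropped_constant=const,
    )


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor per feature: 1 / (1 - R^2_j).

    R^2_j is the coefficient of determination from regressing feature j on
    all other features (with intercept).  Exact collinearity yields inf.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d < 2:
        raise ValueError("need >= 2 features")
    out = np.empty(d)
    for j in range(d):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[j] = np.nan
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """MAE degradation per feature under column permutation.

    importance_j = mean over repeats of (MAE with column j shuffled) minus
    the unpermuted MAE.  ``model`` is a trained
    :class:`~snarpred.model_zoo.TrainedModel` or any object with ``predict``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def _predict(M):
        if isinstance(model, model_zoo.TrainedModel):
            return np.asarray(model_zoo.predict(model, M).mean)
        return np.asarray(model.predict(M))

    baseline = float(np.mean(np.abs(_predict(X) - y)))
    d = X.shape[1]
    imp = np.zeros(d)
    for j in range(d):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            deltas.append(float(np.mean(np.abs(_predict(Xp) - y))) - baseline)
        imp[j] = float(np.mean(deltas))
    return imp


@dataclass
class ImportanceRanking:
    feature_indices: list[int]
    mean_importance: np.ndarray
    ranks: np.ndarray  # n_bootstrap x n_features; rank 1 = most important
    n_bootstrap: int
    seed: int

    def rank_counts(self, feature: int) -> np.ndarray:
        j = self.feature_indices.index(feature)
        return np.bincount(self.ranks[:, j], minlength=len(self.feature_indices) + 1)


def bootstrapped_ranking(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: list[int] | None = None,
    n_bootstrap: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Permutation-importance ranking stability over bootstrap resamples.

    Cluster first (one representative per cluster) and pass the surviving
    column indices as ``feature_indices``; the model is refit on each
    bootstrap resample of the rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_indices is None:
        feature_indices = list(range(X.shape[1]))
    sub = X[:, feature_indices]
    rng = np.random.default_rng(seed)
    n = y.size
    importances, ranks = [], []
    attempts = 0
    while len(ranks) < n_bootstrap and attempts < 3 * n_bootstrap:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        Xb, yb = sub[idx], y[idx]
        if any(np.ptp(Xb[:, j]) == 0 for j in range(Xb.shape[1])):
            warnings.warn("resample dropped a feature's variance to zero; skipped", stacklevel=2)
            continue
        model = model_zoo.fit(config, Xb, yb)
        imp = permutation_importance(
            model, Xb, yb, n_repeats=n_repeats, seed=int(rng.integers(2**31))
        )
        importances.append(imp)
        # rank 1 = largest importance
        order = np.argsort(-imp, kind="stable")
        rank = np.empty(len(imp), dtype=int)
        rank[order] = np.arange(1, len(imp) + 1)
        ranks.append(rank)
    if len(ranks) < n_bootstrap:
        raise RuntimeError("too many degenerate resamples")
    return ImportanceRanking(
        feature_indices=list(feature_indices),
        mean_importance=np.mean(importances, axis=0),
        ranks=np.asarray(ranks),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
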