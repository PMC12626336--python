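"""Normalization for clustering and PAM module discovery.

The normalization chain is CPM -> log2(x+1) -> column quantile
normalization -> row z-score, producing the z-units displayed in module
heatmaps.  Module discovery is Partitioning Around Medoids (k-medoids,
BUILD + SWAP) on the Pearson distance d = 1 - r, with fuzzy membership
weights proportional to inverse medoid distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .diffexpr import cpm as _cpm
from .diffexpr import size_factors as _size_factors

__all__ = [
    "quantile_normalize", "normalize_for_clustering", "pearson_distance",
    "PAMClusterer", "pam_cluster", "subcluster_order",
]


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Column quantile normalization.

    Every column is mapped onto the reference distribution (the mean of
    the sorted columns); ties within a column receive the average of the
    tied ranks' reference values.
    """
    arr = np.asarray(mat, dtype=float)
    n, m = arr.shape
    order = np.argsort(arr, axis=0, kind="mergesort")
    reference = np.mean(np.take_along_axis(arr, order, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        # average reference value over tied ranks
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = reference[lo] * (1 - frac) + reference[hi] * frac
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def normalize_for_clustering(counts: pd.DataFrame,
                             sf: pd.Series | None = None,
                             z_score: bool = True) -> pd.DataFrame:
    """CPM -> log2(x+1) -> quantile normalize -> row z-score.

    Intended for the significant-feature subset (DE genes or DA peaks).
    Constant rows are z-scored to all zeros with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize for clustering")
    if sf is None:
        sf = _size_factors(counts)
    log_cpm = np.log2(_cpm(counts, sf) + 1.0)
    qn = quantile_normalize(log_cpm)
    if not z_score:
        return qn
    arr = qn.to_numpy()
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows z-scored to 0")
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=counts.index, columns=counts.columns)


def pearson_distance(mat) -> np.ndarray:
    """Pearson distance matrix d = 1 - r, in [0, 2] with zero diagonal.

    Zero-variance rows are assigned distance 1 to every other row (the
    uncorrelated convention) with a warning.
    """
    arr = np.asarray(mat, dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 columns for Pearson distance")
    sd = arr.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows; distance set to 1")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(arr)
    d = 1.0 - r
    d[flat, :] = 1.0
    d[:, flat] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


class PAMClusterer(ClusterMixin, BaseEstimator):
    """Partitioning Around Medoids with fuzzy membership weights.

    Parameters
    ----------
    n_clusters : int
        Number of modules k.
    metric : {"pearson", "precomputed", "euclidean"}
        With "pearson" (default) X rows are profiles and the distance is
        1 - Pearson r; "precomputed" expects a square distance matrix.
    max_iter : int
        Cap on SWAP iterations (each strictly decreases the total cost, so
        termination is guaranteed regardless).
    random_state : int or None
        Unused (the algorithm is deterministic); accepted for pipeline
        compatibility.

    Attributes
    ----------
    medoid_indices_ : (k,) row indices of the medoids
    labels_ : (n,) hard assignment = argmax of membership_
    membership_ : (n, k) fuzzy weights, rows sum to 1
    inertia_ : total within-cluster dissimilarity at the optimum
    cost_history_ : cost after BUILD and each SWAP step (non-increasing)
    """

    def __init__(self, n_clusters: int = 6, metric: str = "pearson",
                 max_iter: int = 200, random_state=None):
        self.n_clusters = n_clusters
        self.metric = metric
        self.max_iter = max_iter
        self.random_state = random_state

    def _distances(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.metric == "precomputed":
            if X.shape[0] != X.shape[1]:
                raise ValueError("precomputed distance matrix must be square")
            return X
        if self.metric == "pearson":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return pearson_distance(X)
        if self.metric == "euclidean":
            from scipy.spatial.distance import cdist

            return cdist(X, X)
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit(self, X, y=None):
        D = self._distances(X)
        n = D.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must lie in [1, {n}]")

        # BUILD: first medoid minimizes total distance, then greedy additions
        medoids = [int(np.argmin(D.sum(axis=1)))]
        while len(medoids) < k:
            current = D[:, medoids].min(axis=1)
            gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        cost = float(D[:, medoids].min(axis=1).sum())
        history = [cost]

        # SWAP: steepest-descent swaps until no improvement
        for _ in range(self.max_iter):
            best_delta, best_swap = -1e-12, None
            med_set = set(medoids)
            dist_to_meds = D[:, medoids]                    # (n, k)
            nearest = dist_to_meds.min(axis=1)
            second = (np.partition(dist_to_meds, 1, axis=1)[:, 1]
                      if k > 1 else np.full(n, np.inf))
            for mi, m in enumerate(medoids):
                others = np.where(dist_to_meds[:, mi] == nearest, second, nearest)
                for h in range(n):
                    if h in med_set:
                        continue
                    delta = float(np.minimum(others, D[:, h]).sum()) - cost
                    if delta < best_delta:
                        best_delta, best_swap = delta, (mi, h)
            if best_swap is None:
                break
            medoids[best_swap[0]] = best_swap[1]
            cost = float(D[:, medoids].min(axis=1).sum())
            history.append(cost)

        medoids = sorted(medoids)
        dist_to_meds = D[:, medoids]
        self.medoid_indices_ = np.asarray(medoids)
        self.membership_ = _fuzzy_weights(dist_to_meds)
        self.labels_ = self.membership_.argmax(axis=1)
        self.inertia_ = float(dist_to_meds.min(axis=1).sum())
        self.cost_history_ = history
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:])), \
            "PAM cost increased across SWAP iterations"
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        check_is_fitted(self, "medoid_indices_")
        D = self._distances(X)
        return D[:, self.medoid_indices_].argmin(axis=1)


def _fuzzy_weights(dist_to_meds: np.ndarray) -> np.ndarray:
    """Membership w_c proportional to 1/d(x, medoid_c); exact matches get w=1."""
    n, k = dist_to_meds.shape
    w = np.empty((n, k))
    for i in range(n):
        d = dist_to_meds[i]
        zero = d <= 1e-12
        if zero.any():
            w[i] = zero / zero.sum()
        else:
            inv = 1.0 / d
            w[i] = inv / inv.sum()
    return w


def pam_cluster(mat: pd.DataFrame, k: int, seed: int | None = None,
                metric: str = "pearson") -> pd.DataFrame:
    """Cluster normalized feature profiles into k modules (1-based labels).

    Thin wrapper over :class:`PAMClusterer`; returns a frame indexed by
    feature with module label, fuzzy weights, distance to own medoid and a
    medoid flag.
    """
    est = PAMClusterer(n_clusters=k, metric=metric, random_state=seed).fit(mat)
    D = est._distances(mat)
    own = D[np.arange(len(mat)), est.medoid_indices_[est.labels_]]
    out = pd.DataFrame({
        "module": est.labels_ + 1,
        "medoid": [i in set(est.medoid_indices_) for i in range(len(mat))],
        "dist_to_medoid": own,
    }, index=mat.index)
    for c in range(est.n_clusters):
        out[f"w{c + 1}"] = est.membership_[:, c]
    out.attrs["medoid_features"] = list(np.asarray(mat.index)[est.medoid_indices_])
    out.attrs["inertia"] = est.inertia_
    return out


def subcluster_order(module_mat: pd.DataFrame):
    """Display row order within a module via average-linkage clustering.

    Average linkage on the module's Pearson distances; returns the leaf
    order (a permutation of the module's features) and the linkage matrix.
    """
    n = len(module_mat)
    if n == 0:
        raise ValueError("empty module")
    if n == 1:
        return list(module_mat.index), None
    D = pearson_distance(module_mat)
    Z = _average_linkage(squareform(D, checks=False))
    order = leaves_list(Z)
    return list(np.asarray(module_mat.index)[order]), Z
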