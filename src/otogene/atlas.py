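"""Interpretability geometry: 23-group k-means and a 3-D manifold map.

Labeled training audiograms are standardized (z-score per feature — age in
years and thresholds in dB live on different scales), partitioned into 23
groups with k-means, and embedded into three dimensions with UMAP so a new
patient can be placed as a single marker among the genetically confirmed
cases without recomputing the map.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # umap warns about numba parallelism
    import umap

from .preprocess import N_FEATURES

DEFAULT_K = 23
DEFAULT_SEED = 42


class AudiogramAtlas(BaseEstimator):
    """Standardize -> k-means (k=23) -> 3-D UMAP, with out-of-sample placement.

    Parameters
    ----------
    n_clusters : int, default 23 (one group per panel gene).
    n_neighbors, min_dist : UMAP locality parameters.
    n_init : k-means restarts (best inertia kept).
    random_state : seeds both k-means and UMAP; fixed seed gives
        reproducible coordinates.

    Attributes
    ----------
    centroids_ : (k, 11) cluster centres in standardized feature space.
    labels_ : training cluster assignment per audiogram.
    inertia_ : total within-cluster sum of squares.
    embedding_ : (n, 3) training coordinates.
    """

    def __init__(
        self,
        n_clusters: int = DEFAULT_K,
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        n_init: int = 10,
        random_state: int = DEFAULT_SEED,
    ):
        self.n_clusters = n_clusters
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise ValueError(
                f"need >= {self.n_clusters} distinct points, got {len(np.unique(X, axis=0))}"
            )
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.kmeans_ = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            tol=1e-6,
            random_state=self.random_state,
        ).fit(Z)
        self.centroids_ = self.kmeans_.cluster_centers_
        # reassign to guarantee nearest-centroid consistency with the
        # documented tie-break (lowest cluster index wins)
        self.labels_ = np.argmin(cdist(Z, self.centroids_), axis=1)
        self.inertia_ = float(
            np.sum((Z - self.centroids_[self.labels_]) ** 2)
        )
        n_neighbors = int(min(self.n_neighbors, len(X) - 1))
        self.umap_ = umap.UMAP(
            n_components=3,
            n_neighbors=n_neighbors,
            min_dist=self.min_dist,
            random_state=self.random_state,
        ).fit(Z)
        self.embedding_ = np.asarray(self.umap_.embedding_, dtype=float)
        return self

    def assign(self, X) -> np.ndarray:
        """Nearest-centroid cluster index (ties -> lower index)."""
        check_is_fitted(self, "centroids_")
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return np.argmin(cdist(Z, self.centroids_), axis=1)

    def transform(self, X) -> np.ndarray:
        """Out-of-sample 3-D coordinates via the embedding's native transform."""
        check_is_fitted(self, "umap_")
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return np.asarray(self.umap_.transform(Z), dtype=float)

    def place_patient(self, x) -> tuple[int, np.ndarray]:
        """(cluster index, 3-D coordinate) for one feature vector — the
        dashboard's red patient marker."""
        x = np.asarray(x, dtype=float).reshape(1, N_FEATURES)
        return int(self.assign(x)[0]), self.transform(x)[0]


def fit_clusters(X, k: int = DEFAULT_K, seed: int = DEFAULT_SEED, n_init: int = 10) -> KMeans:
    """Standalone k-means on standardized features (best of ``n_init``)."""
    Z = StandardScaler().fit_transform(np.asarray(X, dtype=float))
    return KMeans(n_clusters=k, n_init=n_init, tol=1e-6, random_state=seed).fit(Z)


def embed(X, n_neighbors: int = 15, min_dist: float = 0.1, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Standalone 3-D embedding of standardized features."""
    X = np.asarray(X, dtype=float)
    Z = StandardScaler().fit_transform(X)
    reducer = umap.UMAP(
        n_components=3,
        n_neighbors=int(min(n_neighbors, len(X) - 1)),
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(Z), dtype=float)


def cluster_composition(assignments: Sequence[int], genes: Sequence[str]) -> pd.DataFrame:
    """Cluster x gene count table; marginals equal the dataset totals."""
    df = pd.DataFrame({"cluster": list(assignments), "gene": list(genes)})
    return df.groupby(["cluster", "gene"]).size().unstack(fill_value=0)


def cluster_support(
    assignments: Sequence[int], genes: Sequence[str], cluster: int, gene: str
) -> float:
    """Fraction of a cluster's audiograms labeled with ``gene`` (0 if the
    cluster is empty)."""
    a = np.asarray(list(assignments))
    g = np.asarray(list(genes), dtype=object)
    in_cluster = a == cluster
    if in_cluster.sum() == 0:
        return 0.0
    return float((g[in_cluster] == gene).mean())
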