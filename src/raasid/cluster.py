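"""Unsupervised clustering of the standardized log biomarker panel.

Three algorithms (k-means, Ward hierarchical, fuzzy c-means) are fitted over
a grid of cluster counts; the method/k pair with the largest mean silhouette
width wins. Principal components of the standardized panel support visual
inspection, and a canonical relabeling orders clusters by ascending mean log
angiotensin I so that cluster 1 is the no-RAAS-drug-like cluster and the top
cluster is ACE-inhibitor-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

METHOD_ORDER = ("kmeans", "hierarchical", "fuzzy")


@dataclass
class ClusterSolution:
    """A fitted hard (or defuzzified) partition.

    ``labels`` are 1-based in ``1..k``; ``centroids`` live in the space the
    model was fitted in (standardized log biomarkers). ``memberships`` is the
    row-stochastic n x k matrix for fuzzy fits, None otherwise.
    """

    method: str
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette: float | None = None
    memberships: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or uniq.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if uniq.size != self.k:
            raise ValueError("every cluster must be non-empty")
        if self.memberships is not None:
            m = np.asarray(self.memberships, dtype=float)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("membership rows must sum to 1")
            self.memberships = m


@dataclass
class SelectionReport:
    """Silhouette scores over the (method, k) grid with the argmax pair."""

    grid: pd.DataFrame  # columns: method, k, silhouette, error
    best_method: str
    best_k: int
    best_solution: ClusterSolution
    solutions: dict[tuple[str, int], ClusterSolution] = field(default_factory=dict)


@dataclass
class PCADecomposition:
    """Eigen-structure of the standardized panel's covariance."""

    loadings: np.ndarray  # 3 x 3, rows = components
    variance_fractions: np.ndarray  # descending, sums to 1
    scores: np.ndarray  # n x 3


def _centroids_and_inertia(X: np.ndarray, labels: np.ndarray, k: int):
    centroids = np.vstack([X[labels == j + 1].mean(axis=0) for j in range(k)])
    inertia = float(
        sum(
            ((X[labels == j + 1] - centroids[j]) ** 2).sum()
            for j in range(k)
        )
    )
    return centroids, inertia


def kmeans_fit(
    X: np.ndarray, k: int, restarts: int = 25, seed: int = 0
) -> ClusterSolution:
    """Lloyd k-means with k-means++ starts, best of ``restarts`` by inertia."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {X.shape[0]}")
    if k < 2:
        raise ValueError("k must be at least 2")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts, algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(int) + 1
    return ClusterSolution(
        method="kmeans",
        k=k,
        labels=labels,
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
    )


def hierarchical_fit(X: np.ndarray, k: int) -> ClusterSolution:
    """Agglomerative clustering, Ward linkage on Euclidean distance, cut at k."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {X.shape[0]}")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(X)
    labels = model.labels_.astype(int) + 1
    centroids, inertia = _centroids_and_inertia(X, labels, k)
    return ClusterSolution(
        method="hierarchical", k=k, labels=labels, centroids=centroids,
        inertia=inertia,
    )


def fuzzy_cmeans_fit(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterSolution:
    """Standard fuzzy c-means with fuzzifier ``m``.

    Alternates membership and centroid updates until the largest membership
    change drops below ``tol``. Non-convergence within ``max_iter`` yields a
    flagged (``converged=False``) result rather than an exception. Hard labels
    are the membership argmax.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)
    converged = False
    centroids = np.empty((k, X.shape[1]))
    for _ in range(max_iter):
        W = U**m
        centroids = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        exponent = 1.0 / (m - 1.0)
        inv = d2 ** (-exponent)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        # points coincident with a centroid get full membership there
        hits = d2 < 1e-24
        if hits.any():
            rows = hits.any(axis=1)
            U_new[rows] = hits[rows] / hits[rows].sum(axis=1, keepdims=True)
        change = np.abs(U_new - U).max()
        U = U_new
        if change < tol:
            converged = True
            break
    labels = U.argmax(axis=1) + 1
    # repair empty hard clusters by assigning the point with highest
    # membership for the empty cluster
    for j in range(1, k + 1):
        if not (labels == j).any():
            labels[U[:, j - 1].argmax()] = j
    _, inertia = _centroids_and_inertia(X, labels, k)
    return ClusterSolution(
        method="fuzzy",
        k=k,
        labels=labels,
        centroids=centroids,
        inertia=inertia,
        memberships=U,
        converged=converged,
    )


def silhouette_mean(X: np.ndarray, labels: np.ndarray):
    """Mean silhouette width and per-point widths.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance (excluding self) and b the smallest mean distance to another
    cluster; singleton-cluster points score 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    widths = silhouette_samples(X, labels)
    return float(widths.mean()), widths


def select_clustering(
    X: np.ndarray,
    methods: tuple[str, ...] = METHOD_ORDER,
    k_range: range | tuple[int, ...] = range(2, 7),
    seed: int = 0,
    restarts: int = 25,
) -> SelectionReport:
    """Fit every (method, k) cell and pick the largest mean silhouette.

    Ties break toward smaller k, then by method order kmeans > hierarchical >
    fuzzy. Cells whose fit fails are recorded with the error message and
    excluded from the argmax.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    solutions: dict[tuple[str, int], ClusterSolution] = {}
    for method in methods:
        if method not in METHOD_ORDER:
            raise ValueError(f"unknown clustering method {method!r}")
    for k in k_range:
        for method in methods:
            try:
                if method == "kmeans":
                    sol = kmeans_fit(X, k, restarts=restarts, seed=seed)
                elif method == "hierarchical":
                    sol = hierarchical_fit(X, k)
                else:
                    sol = fuzzy_cmeans_fit(X, k, seed=seed)
                score, _ = silhouette_mean(X, sol.labels)
                sol.silhouette = score
                solutions[(method, k)] = sol
                rows.append(
                    {"method": method, "k": k, "silhouette": score, "error": ""}
                )
            except ValueError as exc:  # propagate per-cell, exclude from argmax
                rows.append(
                    {"method": method, "k": k, "silhouette": np.nan,
                     "error": str(exc)}
                )
    grid = pd.DataFrame(rows, columns=["method", "k", "silhouette", "error"])
    valid = grid.dropna(subset=["silhouette"])
    if valid.empty:
        raise ValueError("no (method, k) cell could be fitted")
    ranked = valid.assign(
        method_rank=valid["method"].map(METHOD_ORDER.index)
    ).sort_values(
        ["silhouette", "k", "method_rank"], ascending=[False, True, True]
    )
    best = ranked.iloc[0]
    return SelectionReport(
        grid=grid,
        best_method=str(best["method"]),
        best_k=int(best["k"]),
        best_solution=solutions[(str(best["method"]), int(best["k"]))],
        solutions=solutions,
    )


def pca_decompose(X: np.ndarray) -> PCADecomposition:
    """Principal components of the standardized panel.

    Variance fractions are eigenvalues of the column covariance divided by
    its trace; rank-deficient input yields zero fractions, not an error.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 observations")
    pca = PCA(n_components=X.shape[1]).fit(X)
    fractions = pca.explained_variance_ratio_.copy()
    return PCADecomposition(
        loadings=pca.components_.copy(),
        variance_fractions=fractions,
        scores=pca.transform(X),
    )


def identify_drug_clusters(labels: np.ndarray, X_log: np.ndarray) -> dict:
    """Map a 3-cluster partition to its pharmacological signatures.

    The no-RAAS-drug-like cluster has the lowest mean log angiotensin I;
    among the remaining drug-signature clusters, angiotensin II separates the
    classes robustly (ACE inhibition depletes it, receptor blockade elevates
    it): the ACEi-like cluster is the one with the lowest mean log ang II,
    the ARB-like cluster the one with the highest.
    """
    labels = np.asarray(labels)
    X_log = np.asarray(X_log, dtype=float)
    uniq = np.unique(labels)
    if uniq.size != 3:
        raise ValueError("drug-signature identification expects 3 clusters")
    ang1 = {c: X_log[labels == c, 0].mean() for c in uniq}
    ang2 = {c: X_log[labels == c, 1].mean() for c in uniq}
    acei = min(uniq, key=lambda c: ang2[c])
    arb = max(uniq, key=lambda c: ang2[c])
    non_raas = min(uniq, key=lambda c: ang1[c])
    if len({acei, arb, non_raas}) != 3:
        # degenerate geometry: fall back to assigning the remaining cluster
        remaining = [c for c in uniq if c not in (acei, arb)]
        non_raas = remaining[0]
    return {"non_raas": non_raas, "acei": acei, "arb": arb}


def canonical_relabel(solution: ClusterSolution, X_log: np.ndarray) -> ClusterSolution:
    """Renumber clusters by ascending mean log angiotensin I.

    Cluster 1 then collects the no-RAAS-drug-like profile (lowest ang I) and
    the top cluster the ACE-inhibitor-like profile (highest ang I, following
    the convention that ang I rises most under ACE inhibition). Idempotent and
    invariant to the incoming label permutation.
    """
    X_log = np.asarray(X_log, dtype=float)
    means = np.array(
        [X_log[solution.labels == j + 1, 0].mean() for j in range(solution.k)]
    )
    order = np.argsort(means)  # old (0-based) cluster index in ascending ang1
    new_of_old = np.empty(solution.k, dtype=int)
    new_of_old[order] = np.arange(1, solution.k + 1)
    labels = new_of_old[solution.labels - 1]
    memberships = None
    if solution.memberships is not None:
        memberships = solution.memberships[:, order]
    return ClusterSolution(
        method=solution.method,
        k=solution.k,
        labels=labels,
        centroids=solution.centroids[order],
        inertia=solution.inertia,
        silhouette=solution.silhouette,
        memberships=memberships,
        converged=solution.converged,
    )
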