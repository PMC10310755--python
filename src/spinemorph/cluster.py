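"""Clustering of spines and selection of the cluster number.

k-means (Euclidean) and DBSCAN (Euclidean or Jensen-Shannon on CLDH rows)
are provided, with three ways to pick the cluster count:

* elbow on the within-cluster sum of squares (WSS) curve — the grid value
  of maximum discrete curvature of the min-max-normalized curve;
* the mean silhouette coefficient;
* the max-class-divergence criterion: the expert classes are distributed
  over clusters in a row-stochastic matrix M (M_ij = |cluster_i ∩ class_j|
  / |cluster_i|), and the score is the mean Euclidean distance between
  unordered row pairs, divided by sqrt(2) so disjoint pure clusters score
  exactly 1.  The best k maximizes how differently the clusters are
  composed in terms of expert classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.neighbors import NearestNeighbors

from .cldh import jensen_shannon_distance, pairwise_distance_matrix

NOISE = -1  # DBSCAN noise marker in assignments


@dataclass
class ClusteringResult:
    """Cluster assignments with the algorithm and parameters that made them.

    ``assignments`` maps row index -> cluster id in 1..k, or NOISE (-1) for
    DBSCAN noise points.
    """

    assignments: np.ndarray
    k: int
    algorithm: str
    parameters: dict

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        labels = set(self.assignments.tolist()) - {NOISE}
        if labels and labels != set(range(1, self.k + 1)):
            raise ValueError("cluster ids must be contiguous 1..k")
        if NOISE in set(self.assignments.tolist()) and self.algorithm != "dbscan":
            raise ValueError("noise labels are only allowed for DBSCAN")


@dataclass
class QualityCurve:
    """A model-selection curve: criterion score per parameter grid value."""

    grid: np.ndarray
    scores: np.ndarray
    criterion: str

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.grid) != len(self.scores):
            raise ValueError("grid and scores must align")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def kmeans_cluster(X, k: int, rng=None, n_init: int = 10) -> ClusteringResult:
    """Best-of-``n_init`` k-means partition (Euclidean)."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= len(X):
        raise ValueError(f"k must be in [1, {len(X)}]")
    seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return ClusteringResult(
        assignments=labels + 1, k=k, algorithm="kmeans",
        parameters={"k": k, "n_init": n_init, "inertia": float(km.inertia_)},
    )


def dbscan_cluster(
    X, eps: float, min_neighbors: int = 4, metric: str = "euclidean"
) -> ClusteringResult:
    """Density-based clustering; unassigned points are marked noise.

    ``metric='jensen_shannon'`` is valid only for row-normalized histograms
    (CLDH rows) and reuses the package's scalar JSD via a precomputed
    distance matrix.
    """
    X = np.asarray(X, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if metric == "jensen_shannon":
        if np.any(X < 0) or not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("JSD metric requires normalized histogram rows")
        D = pairwise_distance_matrix(list(X))
        db = DBSCAN(eps=eps, min_samples=min_neighbors, metric="precomputed")
        labels = db.fit_predict(D)
    elif metric == "euclidean":
        db = DBSCAN(eps=eps, min_samples=min_neighbors)
        labels = db.fit_predict(X)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    k = int(labels.max()) + 1 if labels.max() >= 0 else 0
    out = np.where(labels >= 0, labels + 1, NOISE)
    return ClusteringResult(
        assignments=out, k=k, algorithm="dbscan",
        parameters={"eps": eps, "min_neighbors": min_neighbors, "metric": metric},
    )


def wss_curve(X, k_grid, rng=None, n_init: int = 10) -> QualityCurve:
    """Within-cluster sum of squares of the best k-means run, per k."""
    X = np.asarray(X, dtype=float)
    k_grid = list(k_grid)
    if not k_grid or any(not 1 <= k <= len(X) for k in k_grid):
        raise ValueError("invalid k grid")
    rng = np.random.default_rng(rng)
    scores = []
    for k in k_grid:
        res = kmeans_cluster(X, int(k), rng=rng, n_init=n_init)
        scores.append(res.parameters["inertia"])
    return QualityCurve(grid=np.asarray(k_grid, float), scores=np.asarray(scores),
                        criterion="wss")


def dbscan_phi_curve(X, eps_grid, metric: str = "euclidean") -> QualityCurve:
    """phi(eps): the number of points whose 3rd-nearest-neighbour distance
    exceeds eps (the DBSCAN analogue of the WSS curve; non-increasing)."""
    X = np.asarray(X, dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 points for 3-NN distances")
    if metric == "jensen_shannon":
        D = pairwise_distance_matrix(list(X))
        d3 = np.sort(D, axis=1)[:, 3]  # column 0 is self-distance 0
    else:
        nn = NearestNeighbors(n_neighbors=4).fit(X)
        dists, _ = nn.kneighbors(X)
        d3 = dists[:, 3]
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    scores = np.array([(d3 > e).sum() for e in eps_grid], dtype=float)
    return QualityCurve(grid=eps_grid, scores=scores, criterion="phi")


def elbow_point(curve: QualityCurve):
    """Grid value at the elbow: the interior point of maximum discrete
    curvature (turning angle) of the min-max-normalized curve.

    Ties break toward the smaller parameter; a perfectly straight curve has
    no elbow and returns the smallest interior point with a warning.
    """
    x, y = curve.grid, curve.scores
    if len(x) < 3:
        raise ValueError("need at least 3 grid points")

    def norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    xn, yn = norm(x), norm(y)
    pts = np.stack([xn, yn], axis=1)
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    lens[lens < 1e-15] = 1e-15
    d = seg / lens[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    angles = np.arccos(cosang)  # one per interior point
    if np.all(angles < 1e-6):
        warnings.warn("no elbow: curve is straight", stacklevel=2)
        return float(x[1])
    best = int(np.argmax(angles))  # argmax takes the first (smallest k) tie
    return float(x[best + 1])


def silhouette(X, result: ClusteringResult, metric: str = "euclidean") -> float:
    """Mean per-sample silhouette coefficient (Rousseeuw), noise excluded."""
    X = np.asarray(X, dtype=float)
    keep = result.assignments != NOISE
    labels = result.assignments[keep]
    Xk = X[keep]
    k = len(set(labels.tolist()))
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if k >= len(Xk):
        raise ValueError("silhouette needs k < n samples")
    if metric == "jensen_shannon":
        D = pairwise_distance_matrix(list(Xk))
        return float(_sk_silhouette(D, labels, metric="precomputed"))
    return float(_sk_silhouette(Xk, labels, metric=metric))


def class_distribution_matrix(result: ClusteringResult, classes) -> pd.DataFrame:
    """Row-stochastic matrix M of class shares within each cluster
    (rows = clusters, columns = classes; noise points excluded)."""
    classes = pd.Series(classes)
    keep = result.assignments != NOISE
    if len(classes) != len(result.assignments):
        raise ValueError("classes must align with assignments")
    df = pd.DataFrame({
        "cluster": result.assignments[keep],
        "cls": classes.to_numpy()[keep],
    })
    tab = pd.crosstab(df["cluster"], df["cls"])
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("empty cluster")
    return tab.div(tab.sum(axis=1), axis=0)


def class_divergence_score(result: ClusteringResult, classes) -> float:
    """Max-class-divergence clustering quality score in [0, 1].

    Mean Euclidean distance between unordered row pairs of the
    class-distribution matrix, normalized by sqrt(2) so two disjoint pure
    clusters score exactly 1 and identical compositions score 0.
    """
    M = class_distribution_matrix(result, classes)
    if len(M) < 2:
        raise ValueError("need at least 2 clusters")
    rows = M.to_numpy()
    dists = [
        np.linalg.norm(rows[i] - rows[j])
        for i, j in itertools.combinations(range(len(rows)), 2)
    ]
    return float(np.mean(dists) / np.sqrt(2.0))


def select_cluster_number(
    X, classes=None, k_grid=range(2, 16), criterion="divergence",
    rng=None, n_init: int = 10,
):
    """Pick k for k-means by one of three criteria; returns (k*, curve).

    ``divergence`` and ``silhouette`` take the argmax over the grid (ties
    toward smaller k); ``elbow`` applies :func:`elbow_point` to the WSS
    curve.  ``classes`` is required only for the divergence criterion.
    """
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValueError("empty k grid")
    rng = np.random.default_rng(rng)
    if criterion == "elbow":
        curve = wss_curve(X, k_grid, rng=rng, n_init=n_init)
        return int(elbow_point(curve)), curve
    scores = []
    for k in k_grid:
        res = kmeans_cluster(X, k, rng=rng, n_init=n_init)
        if criterion == "silhouette":
            scores.append(silhouette(X, res))
        elif criterion == "divergence":
            if classes is None:
                raise ValueError("divergence criterion requires class labels")
            scores.append(class_divergence_score(res, classes))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    curve = QualityCurve(grid=np.asarray(k_grid, float),
                         scores=np.asarray(scores), criterion=criterion)
    return int(k_grid[int(np.argmax(curve.scores))]), curve


def project_2d(X, method: str = "pca", rng=None):
    """2D coordinates for visualization: PCA (deterministic up to sign) or
    seeded t-SNE."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    if method == "pca":
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
            raise ValueError("rank < 2: PCA projection undefined")
        return PCA(n_components=2).fit_transform(X)
    if method == "tsne":
        seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
        perp = min(30.0, max(2.0, (len(X) - 1) / 3.0))
        return TSNE(n_components=2, random_state=seed, perplexity=perp,
                    init="pca").fit_transform(X)
    raise ValueError(f"unknown method {method!r}")


def pca_reduce(X, variance: float = 0.95):
    """Optional pre-reduction before k-means in classic feature space:
    keep the components explaining ``variance`` of the total variance."""
    X = np.asarray(X, dtype=float)
    return PCA(n_components=variance).fit_transform(X)


def enrichment_tables(result: ClusteringResult, classes):
    """Both normalizations of the cluster-by-class contingency table.

    Returns (class_in_cluster, cluster_in_class): the first divides rows by
    cluster size (class mix of each cluster), the second divides by class
    size (cluster mix of each class); each row sums to 1.
    """
    classes = pd.Series(classes)
    keep = result.assignments != NOISE
    df = pd.DataFrame({
        "cluster": result.assignments[keep],
        "cls": classes.to_numpy()[keep],
    })
    tab = pd.crosstab(df["cluster"], df["cls"])
    if (tab.sum(axis=0) == 0).any():
        raise ValueError("empty class")
    class_in_cluster = tab.div(tab.sum(axis=1), axis=0)
    cluster_in_class = tab.T.div(tab.T.sum(axis=1), axis=0)
    return class_in_cluster, cluster_in_class
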