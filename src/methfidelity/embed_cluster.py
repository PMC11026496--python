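"""PCA-initialized t-SNE embedding, HDBSCAN clustering, DBCV validity.

The embedding follows the PCA-initialization protocol: reduce to
``pca_components`` principal components, then run Barnes–Hut t-SNE seeded
from the first two PCA axes (rescaled to sd 1e-4).  Clusters come from
HDBSCAN with noise relabeled 0 and clusters renumbered 1..K by decreasing
size; cluster stability is quantified by the density-based clustering
validation (DBCV) index, with clusters above 0.25 treated as valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = ["Embedding", "ClusterAssignment", "embed", "cluster", "dbcv",
           "VALIDITY_THRESHOLD"]

#: clusters with a DBCV index above this are treated as valid
VALIDITY_THRESHOLD = 0.25


@dataclass
class Embedding:
    sample_ids: list[str]
    coords: np.ndarray  # n x 2
    params: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=["x", "y"])


@dataclass
class ClusterAssignment:
    labels: pd.Series           # per-sample int, 0 = noise
    n_clusters: int
    validity: pd.Series | None = None   # per-cluster DBCV index
    overall_validity: float | None = None


def embed(
    beta: pd.DataFrame,
    perplexity: float = 15,
    theta: float = 0.5,
    eei: int = 200,
    pca_components: int = 20,
    seed: int = 0,
) -> Embedding:
    """Embed samples (columns of ``beta``) in 2-D by PCA-initialized t-SNE.

    No feature selection is applied: the full probe set enters the PCA.
    ``eei`` (early-exaggeration iterations) is recorded in the embedding
    hyperparameters; the Barnes–Hut backend fixes the length of its
    exploration phase internally.
    """
    X = beta.to_numpy().T  # samples x probes
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity={perplexity} too large for n={n}; need perplexity < (n-1)/3"
        )
    if n < 3 * perplexity:
        warnings.warn("fewer than 3*perplexity samples; embedding may be unstable")

    k = min(pca_components, n - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    Xp = pca.fit_transform(X)
    init = Xp[:, :2].copy()
    init = init / init[:, 0].std() * 1e-4  # standard small-variance init

    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        init=init,
        method="barnes_hut",
        random_state=seed,
    )
    coords = tsne.fit_transform(Xp)
    return Embedding(
        sample_ids=list(beta.columns),
        coords=np.asarray(coords, dtype=float),
        params=dict(
            perplexity=perplexity, theta=theta, eei=eei,
            pca_components=k, seed=seed,
        ),
    )


def cluster(embedding: Embedding, min_cluster_size: int = 4) -> ClusterAssignment:
    """HDBSCAN on the embedding; noise -> 0, clusters 1..K by decreasing size."""
    X = embedding.coords
    if len(X) < min_cluster_size:
        raise ValueError("fewer points than min_cluster_size")
    raw = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_cluster_size,
        allow_single_cluster=True, copy=True,
    ).fit_predict(X)

    sizes = pd.Series(raw[raw >= 0]).value_counts()
    # renumber by decreasing size, ties broken by original label for stability
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap.get(c, 0) for c in raw])
    return ClusterAssignment(
        labels=pd.Series(labels, index=embedding.sample_ids, name="cluster"),
        n_clusters=len(order),
    )


# ---------------------------------------------------------------------------
# DBCV (density-based clustering validation)
# ---------------------------------------------------------------------------

def _core_distances(X: np.ndarray, eps: float) -> np.ndarray:
    """All-points-core-distance of each point w.r.t. its cluster members."""
    n, d = X.shape
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    D = np.clip(D, eps, None)
    inv = (1.0 / D) ** d
    inv[~np.isfinite(inv)] = 0.0
    s = inv.sum(axis=1) / (n - 1)
    return s ** (-1.0 / d)


def _mutual_reach(X: np.ndarray, core: np.ndarray, eps: float) -> np.ndarray:
    D = cdist(X, X)
    return np.maximum(np.maximum.outer(core, core), np.clip(D, eps, None))


def _sparseness_and_internal(X: np.ndarray, eps: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Density sparseness of a cluster: max internal edge of the mutual-
    reachability MST; also returns core distances and an internal-node mask."""
    core = _core_distances(X, eps)
    mr = _mutual_reach(X, core, eps)
    mst = minimum_spanning_tree(mr).toarray()
    edges = mst + mst.T
    degree = (edges > 0).sum(axis=1)
    internal = degree > 1
    if internal.sum() >= 2:
        sub = edges[np.ix_(internal, internal)]
        weights = sub[sub > 0]
        dsc = float(weights.max()) if weights.size else float(edges.max())
    else:
        dsc = float(edges.max())
    if not internal.any():  # 2-point cluster: both endpoints count
        internal = np.ones(len(X), dtype=bool)
    return dsc, core, internal


def dbcv(
    embedding: Embedding | np.ndarray,
    labels,
    eps: float = 1e-10,
) -> tuple[pd.Series, float]:
    """Density-based clustering validation index.

    For each cluster the density sparseness (max internal edge of the
    mutual-reachability minimum spanning tree) is compared against the
    density separation to the closest other cluster (min mutual-reachability
    distance between internal nodes).  Per-cluster validity is

        V(C) = (min_sep - sparseness) / max(min_sep, sparseness),

    in [-1, 1]; the overall index is the size-weighted average over all
    points (noise contributes weight but zero validity).  Clusters of
    identical points are handled by an epsilon distance floor.
    """
    X = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    labels = np.asarray(pd.Series(labels).to_numpy())
    cluster_ids = sorted(c for c in np.unique(labels) if c != 0)
    if len(cluster_ids) == 0:
        return pd.Series(dtype=float), 0.0
    for cid in cluster_ids:
        if (labels == cid).sum() < 2:
            raise ValueError(f"cluster {cid} has fewer than 2 points")

    info = {}
    for cid in cluster_ids:
        pts = X[labels == cid]
        if cdist(pts, pts).max() <= eps:
            warnings.warn(f"cluster {cid} has identical points; epsilon floor applied")
        dsc, core, internal = _sparseness_and_internal(pts, eps)
        info[cid] = (pts, dsc, core, internal)

    validity = {}
    n_total = len(labels)
    overall = 0.0
    for cid in cluster_ids:
        pts_i, dsc_i, core_i, int_i = info[cid]
        if len(cluster_ids) == 1:
            # no other cluster to separate from: compare against spread of
            # the full point set so a lone tight cluster still scores high
            sep = float(np.clip(cdist(X, X), eps, None).max())
        else:
            sep = np.inf
            for cj in cluster_ids:
                if cj == cid:
                    continue
                pts_j, _, core_j, int_j = info[cj]
                D = np.clip(cdist(pts_i[int_i], pts_j[int_j]), eps, None)
                reach = np.maximum(
                    D, np.maximum.outer(core_i[int_i], core_j[int_j])
                )
                sep = min(sep, float(reach.min()))
        v = (sep - dsc_i) / max(sep, dsc_i)
        validity[cid] = v
        overall += (labels == cid).sum() / n_total * v
    return pd.Series(validity, name="dbcv"), float(overall)
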