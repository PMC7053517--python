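"""Consensus cell phenotyping.

Cells are clustered three independent ways over the phenotypic markers:

* ``kmeans`` — Lloyd's K-means; K either fixed or chosen by silhouette.
* ``phenograph`` — graph community detection in the PhenoGraph style:
  k-nearest-neighbour graph, Jaccard edge weights from shared-neighbour
  overlap, Leiden modularity optimisation.
* ``clusterx`` — density-peak clustering (local density plus
  distance-to-higher-density, automatic centre selection), the published
  basis of ClusterX.

Each method's clusters are summarised by their per-marker mean z-score
and labelled through an explicit marker rulebook; a cell keeps a
phenotype only when at least two of the three methods agree on it,
otherwise it is discarded.  Within each phenotype a second, functional
clustering over the functional markers (Tcy cells use a personalised
panel) yields functional subpopulations annotated by the same rulebook
mechanism.
"""

from __future__ import annotations

import logging
import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .panel import (
    FUNCTIONAL_MARKERS,
    PHENOTYPIC_MARKERS,
    TCY_FUNCTIONAL_MARKERS,
    z_cols,
)
from .rules import Rulebook, UNASSIGNED

logger = logging.getLogger(__name__)

DISCARDED = "discarded"
METHODS = ("kmeans", "phenograph", "clusterx")


# ---------------------------------------------------------------------------
# clustering methods
# ---------------------------------------------------------------------------

def kmeans_cluster(X: np.ndarray, n_clusters: int | None = None,
                   k_range: tuple[int, int] = (10, 30),
                   seed: int | None = None) -> np.ndarray:
    """K-means labels; K by silhouette sweep over ``k_range`` when not fixed."""
    X = np.asarray(X, float)
    if n_clusters is None:
        lo, hi = k_range
        hi = min(hi, len(X) - 1)
        best_k, best_s = None, -np.inf
        rng = np.random.default_rng(seed)
        sample = min(len(X), 2000)
        for k in range(lo, hi + 1):
            labels = KMeans(n_clusters=k, n_init=4, random_state=seed).fit_predict(X)
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(
                X, labels, sample_size=sample,
                random_state=int(rng.integers(2**31)),
            )
            if s > best_s:
                best_k, best_s = k, s
        n_clusters = best_k if best_k is not None else lo
        logger.info("kmeans: silhouette selected K=%d", n_clusters)
    return KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit_predict(X)


def _jaccard_knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    n = len(X)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    # keep only pairs that are kNN edges in at least one direction
    knn_edge = np.asarray(A[r, c]).ravel() + np.asarray(A[c, r]).ravel()
    keep = knn_edge > 0
    r, c, shared = r[keep], c[keep], shared[keep]
    jac = shared / (2 * k - shared)
    g = ig.Graph(n=n, edges=list(zip(r.tolist(), c.tolist())))
    g.es["weight"] = jac.tolist()
    return g


def phenograph_cluster(X: np.ndarray, k: int = 30,
                       seed: int | None = None) -> np.ndarray:
    """kNN-Jaccard graph + Leiden modularity communities."""
    X = np.asarray(X, float)
    if len(X) < 2:
        raise ValueError("need at least 2 cells to cluster")
    g = _jaccard_knn_graph(X, k)
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, weights="weight",
        seed=0 if seed is None else int(seed), n_iterations=2,
    )
    return np.asarray(part.membership)


def density_peak_cluster(X: np.ndarray, dc_quantile: float = 0.02,
                         n_clusters: int | None = None,
                         gamma_sd: float = 4.0,
                         embed: str | None = "umap",
                         seed: int | None = None) -> np.ndarray:
    """Density-peak clustering (Rodriguez-Laio style) on an embedding.

    Following common cytometry practice, the high-dimensional marker
    space is first reduced to a 2-D map (``embed="umap"``; ``None``
    clusters the raw coordinates) where density is meaningful.  Local
    density rho is a Gaussian-kernel count at bandwidth ``dc`` (the
    ``dc_quantile`` quantile of pairwise distances); delta is the
    distance to the nearest point of higher density.  Centres are either
    the top ``n_clusters`` points by gamma = rho_norm * delta_norm, or,
    automatically, the gamma outliers (above mean + ``gamma_sd`` sd).
    Remaining points inherit the cluster of their nearest denser
    neighbour, in decreasing-density order.
    """
    X = np.asarray(X, float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if embed == "umap" and X.shape[1] > 2 and n > 20:
        import umap

        X = umap.UMAP(
            n_components=2, random_state=0 if seed is None else int(seed),
            n_neighbors=min(30, n - 1),
        ).fit_transform(X)
    elif embed not in (None, "umap"):
        raise ValueError(f"unknown embedding {embed!r}")
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X))
    tri = D[np.triu_indices(n, k=1)]
    dc = np.quantile(tri, dc_quantile)
    if dc <= 0:
        dc = tri[tri > 0].min() if np.any(tri > 0) else 1.0
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1.0

    order = np.argsort(-rho, kind="stable")
    delta = np.empty(n)
    nearest_denser = np.full(n, -1)
    delta[order[0]] = D[order[0]].max()
    for pos in range(1, n):
        i = order[pos]
        denser = order[:pos]
        j = denser[np.argmin(D[i, denser])]
        delta[i] = D[i, j]
        nearest_denser[i] = j

    rho_n = (rho - rho.min()) / (rho.max() - rho.min() + 1e-300)
    delta_n = delta / (delta.max() + 1e-300)
    gamma = rho_n * delta_n
    if n_clusters is not None:
        centers = np.argsort(-gamma)[:n_clusters]
    else:
        thr = gamma.mean() + gamma_sd * gamma.std()
        centers = np.flatnonzero(gamma > thr)
        if centers.size == 0:
            centers = np.array([int(np.argmax(gamma))])
    labels = np.full(n, -1)
    for ci, c in enumerate(centers):
        labels[c] = ci
    for i in order:
        if labels[i] < 0:
            labels[i] = labels[nearest_denser[i]]
    return labels


def cluster_three_ways(
    X: np.ndarray,
    seed: int | None = None,
    kmeans_k: int | None = None,
    kmeans_range: tuple[int, int] = (10, 30),
    knn: int = 30,
    dp_clusters: int | None = None,
) -> dict[str, np.ndarray]:
    """Run the three clustering methods; returns method -> label vector."""
    X = np.asarray(X, float)
    if len(X) < 2:
        raise ValueError("need at least 2 cells to cluster")
    out = {
        "kmeans": kmeans_cluster(X, kmeans_k, kmeans_range, seed),
        "phenograph": phenograph_cluster(X, knn, seed),
        "clusterx": density_peak_cluster(X, n_clusters=dp_clusters, seed=seed),
    }
    for m, lab in out.items():
        logger.info("%s: %d clusters", m, len(np.unique(lab)))
    return out


# ---------------------------------------------------------------------------
# annotation and consensus
# ---------------------------------------------------------------------------

def cluster_mean_vectors(Z: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean z-score vector (clusters x markers)."""
    df = Z.copy()
    df["_cluster"] = labels
    return df.groupby("_cluster").mean()


def annotate_clusters(mean_vectors: pd.DataFrame,
                      rulebook: Rulebook) -> dict[int, str]:
    """cluster id -> phenotype (or ``unassigned``) via the rulebook."""
    return {
        int(cid): rulebook.assign(row.to_dict())
        for cid, row in mean_vectors.iterrows()
    }


def consensus_assign(per_method: dict[str, np.ndarray]) -> np.ndarray:
    """Per-cell consensus phenotype: kept iff >=2 methods agree, else
    ``discarded``.  ``unassigned`` votes never win a consensus."""
    methods = list(per_method)
    if len(methods) != 3:
        raise ValueError("consensus expects exactly three labelings")
    mats = [np.asarray(per_method[m], object) for m in methods]
    n = len(mats[0])
    if any(len(m) != n for m in mats):
        raise ValueError("labelings cover different cell sets")
    a, b, c = mats
    out = np.where(a == b, a, np.where(a == c, a, np.where(b == c, b, DISCARDED)))
    out[out == UNASSIGNED] = DISCARDED
    return out


def phenotype_cells(
    table: pd.DataFrame,
    rulebook: Rulebook,
    seed: int | None = None,
    markers: tuple[str, ...] | None = None,
    **cluster_kw,
) -> tuple[pd.DataFrame, dict]:
    """Full consensus phenotyping of a normalized cell table.

    Clusters the phenotypic-marker z-scores three ways, annotates each
    method's clusters through the rulebook, takes the two-of-three
    consensus and writes it to the ``phenotype`` column (``discarded``
    where no two methods agree).  Returns the table and a report dict
    (per-method labelings/annotations and the inclusion fraction).
    """
    if markers is None:
        markers = tuple(
            m for m in PHENOTYPIC_MARKERS if ("z_" + m) in table.columns
        )
    Z = table[z_cols(markers)].copy()
    Z.columns = list(markers)
    labelings = cluster_three_ways(Z.to_numpy(), seed=seed, **cluster_kw)
    per_method_pheno = {}
    annotations = {}
    for method, lab in labelings.items():
        means = cluster_mean_vectors(Z, lab)
        ann = annotate_clusters(means, rulebook)
        annotations[method] = ann
        per_method_pheno[method] = np.asarray(
            [ann[int(l)] for l in lab], object
        )
    consensus = consensus_assign(per_method_pheno)
    out = table.copy()
    out["phenotype"] = consensus
    included = float((consensus != DISCARDED).mean())
    logger.info("consensus phenotyping: %.2f%% of cells included", 100 * included)
    report = {
        "labelings": labelings,
        "annotations": annotations,
        "per_method_phenotype": per_method_pheno,
        "inclusion_fraction": included,
    }
    return out, report


def functional_subcluster(
    table: pd.DataFrame,
    rulebook: Rulebook,
    seed: int | None = None,
    min_cells: int = 20,
    knn: int = 30,
) -> pd.DataFrame:
    """Functional subpopulations within each phenotype.

    Graph-community clustering over the functional markers (Tcy cells use
    the personalised CD8/CD69/OX40/LAG3/TIM3/PD-1/Ki-67 panel), annotated
    with the functional rulebook.  Phenotypes with fewer than
    ``min_cells`` cells form a single functional cluster (warning).
    Writes the ``functional_label`` column.
    """
    out = table.copy()
    out["functional_label"] = pd.NA
    seeds = np.random.SeedSequence(seed)
    pheno_groups = [
        (p, g) for p, g in out.groupby("phenotype", sort=False)
        if p not in (DISCARDED, UNASSIGNED) and not pd.isna(p)
    ]
    for (pheno, g), ss in zip(
        pheno_groups, seeds.spawn(max(len(pheno_groups), 1))
    ):
        markers = TCY_FUNCTIONAL_MARKERS if pheno == "Tcy" else FUNCTIONAL_MARKERS
        markers = tuple(m for m in markers if ("z_" + m) in out.columns)
        Z = g[z_cols(markers)].copy()
        Z.columns = list(markers)
        if len(g) < min_cells:
            warnings.warn(
                f"phenotype {pheno!r} has {len(g)} < {min_cells} cells; "
                "single functional cluster",
                stacklevel=2,
            )
            labels = np.zeros(len(g), dtype=int)
        else:
            labels = phenograph_cluster(
                Z.to_numpy(), k=knn,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
        ann = annotate_clusters(cluster_mean_vectors(Z, labels), rulebook)
        out.loc[g.index, "functional_label"] = [ann[int(l)] for l in labels]
    return out
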