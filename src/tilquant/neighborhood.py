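"""Permutation-based spatial neighborhood analysis.

Within each image (TMA core) the neighborhood of a cell is every other
cell whose centroid lies within a kernel radius (default 30 px, boundary
inclusive).  For an ordered phenotype pair (i, j) the statistic is the
mean number of type-j neighbors per type-i cell.  Its null distribution
is built by shuffling phenotype labels over the fixed cell positions
(which preserves both the spatial point pattern and the composition);
one-sided empirical p-values use the add-one (r+1)/(n+1) estimator.  With
1000 permutations and alpha = 0.001 a call therefore requires the
observed statistic to be more extreme than every permutation.  Per-image
calls are tri-state: proximity (+1), avoidance (-1), non-significant (0).

Calls are integrated across images by the N-weighted average

    P_ij = sum_k c_ijk * N_ijk / sum_k N_ijk

where N_ijk is the geometric mean of the two phenotypes' cell counts in
image k, and |P| is categorized as strong (> 0.75), moderate (> 0.5),
weak (> 0.25) or non-significant.  The statistic is directional
(j-around-i); both directions are computed and integrated separately.

Melanoma cells grow in packed nests that violate the label-shuffle null,
so a dedicated descriptive profile counts, for every other subpopulation,
its cells in contact with melanoma cells, normalized by the geometric
mean of the melanoma and subpopulation abundances over the cores where
the subpopulation occurs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

CATEGORY_THRESHOLDS = (0.75, 0.5, 0.25)  # strong / moderate / weak, strict ">"


@dataclass
class NeighborGraph:
    """Symmetric within-radius adjacency of one image."""

    n_cells: int
    radius: float
    adjacency: sparse.csr_matrix  # boolean, zero diagonal

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def pairs(self) -> set[tuple[int, int]]:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))


def build_neighbor_graph(positions: np.ndarray, radius: float = 30.0) -> NeighborGraph:
    """Connect all and only cell pairs with centroid distance <= radius."""
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be an n x 2 array")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    n = len(pos)
    if n > 1 and len(np.unique(pos, axis=0)) < n:
        warnings.warn("duplicate cell coordinates present", stacklevel=2)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        row = np.concatenate([pairs[:, 0], pairs[:, 1]])
        col = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(len(row), dtype=np.int8)
        adj = sparse.csr_matrix((data, (row, col)), shape=(n, n))
    else:
        adj = sparse.csr_matrix((n, n), dtype=np.int8)
    return NeighborGraph(n_cells=n, radius=float(radius), adjacency=adj)


def _pair_statistic(adj: sparse.csr_matrix, onehot: np.ndarray,
                    counts: np.ndarray, statistic: str) -> np.ndarray:
    """T x T matrix: mean (or total) count of type-j neighbors per type-i cell."""
    neigh = adj @ onehot                     # n x T
    totals = onehot.T @ neigh                # T x T
    if statistic == "total":
        return totals
    return totals / counts[:, None]


def permutation_test_image(
    labels,
    graph: NeighborGraph,
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int | None = None,
    statistic: str = "mean",
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Tri-state interaction calls for one image.

    Returns a long-format frame with one row per ordered evaluable pair:
    columns i, j, c (+1/-1/0), stat, p_proximity, p_avoidance, n_i, n_j.
    Pairs involving a phenotype absent from the image are omitted
    (not evaluable).
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_cells:
        raise ValueError("labels length does not match graph size")
    present = pd.unique(labels)
    if phenotypes is None:
        types = list(present)
    else:
        types = [t for t in phenotypes if t in set(present)]
    if not types:
        raise ValueError("no phenotype present in the image")
    t_index = {t: k for k, t in enumerate(types)}
    codes = np.array([t_index[l] for l in labels])
    T = len(types)
    onehot = np.zeros((len(labels), T))
    onehot[np.arange(len(labels)), codes] = 1.0
    counts = onehot.sum(axis=0)

    adj = graph.adjacency
    obs = _pair_statistic(adj, onehot, counts, statistic)

    rng = np.random.default_rng(seed)
    ge = np.zeros((T, T), dtype=int)   # perms >= observed (proximity side)
    le = np.zeros((T, T), dtype=int)   # perms <= observed (avoidance side)
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        stat = _pair_statistic(adj, onehot[perm], counts, statistic)
        ge += stat >= obs
        le += stat <= obs
    p_prox = (ge + 1) / (n_perm + 1)
    p_avoid = (le + 1) / (n_perm + 1)
    c = np.zeros((T, T), dtype=int)
    c[p_prox < alpha] = 1
    c[p_avoid < alpha] = -1

    rows = []
    for i, ti in enumerate(types):
        for j, tj in enumerate(types):
            rows.append(
                {
                    "i": ti, "j": tj, "c": int(c[i, j]),
                    "stat": float(obs[i, j]),
                    "p_proximity": float(p_prox[i, j]),
                    "p_avoidance": float(p_avoid[i, j]),
                    "n_i": int(counts[i]), "n_j": int(counts[j]),
                }
            )
    return pd.DataFrame(rows)


def analyze_images(
    table: pd.DataFrame,
    radius: float = 30.0,
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int | None = None,
    statistic: str = "mean",
    phenotype_column: str = "phenotype",
) -> pd.DataFrame:
    """Run the per-image permutation test over every core of a cell table.

    Returns the concatenated long-format per-image calls with an image_id
    column; feed the result to :func:`integrate_images`.
    """
    frames = []
    seeds = np.random.SeedSequence(seed).spawn(table["core_id"].nunique())
    for (core, g), ss in zip(table.groupby("core_id", sort=False), seeds):
        graph = build_neighbor_graph(g[["x", "y"]].to_numpy(float), radius)
        res = permutation_test_image(
            g[phenotype_column].to_numpy(), graph, n_perm=n_perm,
            alpha=alpha, seed=int(ss.generate_state(1)[0] % (2**31)),
            statistic=statistic,
        )
        res.insert(0, "image_id", core)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def categorize(p: float) -> str:
    ap = abs(p)
    if ap > CATEGORY_THRESHOLDS[0]:
        return "strong"
    if ap > CATEGORY_THRESHOLDS[1]:
        return "moderate"
    if ap > CATEGORY_THRESHOLDS[2]:
        return "weak"
    return "non-significant"


def integrate_images(per_image: pd.DataFrame) -> pd.DataFrame:
    """Cross-image integration of tri-state calls.

    ``per_image`` needs columns i, j, c, n_i, n_j (one row per ordered
    pair per evaluable image).  Returns one row per ordered pair with the
    number of contributing images M, the weighted score P and its strength
    category.
    """
    required = {"i", "j", "c", "n_i", "n_j"}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per_image is missing columns {sorted(missing)}")
    rows = []
    for (i, j), g in per_image.groupby(["i", "j"], sort=True):
        w = np.sqrt(g["n_i"].to_numpy(float) * g["n_j"].to_numpy(float))
        if w.sum() <= 0:
            logger.warning("pair (%s, %s) has zero total weight; omitted", i, j)
            continue
        p = float((g["c"].to_numpy(float) * w).sum() / w.sum())
        rows.append(
            {"i": i, "j": j, "M": int(len(g)), "P": p, "category": categorize(p)}
        )
    return pd.DataFrame(rows)


def melanoma_neighbor_profile(
    table: pd.DataFrame,
    target_phenotype: str | tuple = "Melanoma",
    radius: float = 30.0,
    phenotype_column: str = "phenotype",
) -> pd.DataFrame:
    """Nest-tolerant contact profile around melanoma cells.

    For each non-target subpopulation: the number of its cells adjacent
    (within radius) to at least one target cell, summed over the cores in
    which the subpopulation appears, divided by the geometric mean of the
    target and subpopulation cell totals over those same cores.
    Subpopulations never adjacent to the target report 0; subpopulations
    absent everywhere are omitted.
    """
    targets = (
        {target_phenotype} if isinstance(target_phenotype, str)
        else set(target_phenotype)
    )
    labels_all = table[phenotype_column]
    if not labels_all.isin(targets).any():
        raise ValueError(f"target phenotype {sorted(targets)} absent from table")

    adjacent: dict[str, int] = {}
    n_sub: dict[str, int] = {}
    n_target: dict[str, int] = {}
    for _, g in table.groupby("core_id", sort=False):
        labels = g[phenotype_column].to_numpy()
        is_target = np.isin(labels, list(targets))
        subpops = [p for p in pd.unique(labels) if p not in targets]
        if not subpops:
            continue
        graph = build_neighbor_graph(g[["x", "y"]].to_numpy(float), radius)
        # cells with >=1 target neighbor
        touch = (graph.adjacency @ is_target.astype(float)) > 0
        for p in subpops:
            mask = labels == p
            adjacent[p] = adjacent.get(p, 0) + int((touch & mask).sum())
            n_sub[p] = n_sub.get(p, 0) + int(mask.sum())
            n_target[p] = n_target.get(p, 0) + int(is_target.sum())
    rows = []
    for p in sorted(adjacent):
        denom = np.sqrt(n_target[p] * n_sub[p])
        rows.append(
            {
                "subpopulation": p,
                "n_adjacent": adjacent[p],
                "n_cells": n_sub[p],
                "n_target": n_target[p],
                "profile": adjacent[p] / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
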