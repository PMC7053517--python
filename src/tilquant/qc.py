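"""Quality control and normalization of single-cell mean fluorescence
intensities (MFIs).

The pipeline starts from a quantified single-cell table (one row per
segmented cell: identifiers, centroid coordinates, one raw MFI column per
marker).  QC removes cells expressing fewer than three markers and markers
expressed in less than 1% of cells, then converts raw MFIs to per-marker
z-scores trimmed to [-5, +5] so that outliers cannot dominate downstream
PCA and clustering.  Filters run cells-first, then markers; z-scores are
computed after both filters over all retained cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import Z_PREFIX

logger = logging.getLogger(__name__)

ID_COLUMNS = ("cell_id", "patient_id", "core_id", "x", "y")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Raw-MFI marker columns of a cell table (everything that is not an
    identifier, coordinate, z-score or annotation column)."""
    reserved = set(ID_COLUMNS) | {
        "phenotype", "functional_label", "activation", "truth_phenotype",
        "truth_functional", "truth_core_status",
    }
    return [
        c for c in table.columns
        if c not in reserved and not c.startswith(Z_PREFIX)
    ]


def filter_cells(
    table: pd.DataFrame,
    min_expressed_markers: int = 3,
    expression_threshold: float = 0.0,
) -> pd.DataFrame:
    """Drop cells that express fewer than ``min_expressed_markers`` markers.

    A marker counts as expressed when its raw MFI is strictly greater than
    ``expression_threshold`` (default 0, i.e. any signal surviving the
    upstream background subtraction).
    """
    if table.empty:
        raise ValueError("cell table is empty")
    markers = marker_columns(table)
    expressed = (table[markers].to_numpy(float) > expression_threshold).sum(axis=1)
    keep = expressed >= min_expressed_markers
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_cells: dropped %d/%d cells with <%d expressed markers",
            n_dropped, len(table), min_expressed_markers,
        )
    return table.loc[keep].reset_index(drop=True)


def filter_markers(table: pd.DataFrame, min_fraction: float = 0.01,
                   expression_threshold: float = 0.0) -> pd.DataFrame:
    """Drop marker columns expressed in fewer than ``min_fraction`` of cells.

    The boundary is inclusive: a marker expressed in exactly
    ``min_fraction`` of cells ("at least 1%") is retained.
    """
    markers = marker_columns(table)
    if not markers:
        raise ValueError("cell table has no marker columns")
    frac = (table[markers].to_numpy(float) > expression_threshold).mean(axis=0)
    dropped = [m for m, f in zip(markers, frac) if f < min_fraction]
    if len(dropped) == len(markers):
        raise ValueError("all markers would be dropped; check the input scale")
    if dropped:
        logger.info("filter_markers: dropped %s", dropped)
    return table.drop(columns=dropped)


def zscore_trim(table: pd.DataFrame, clip: float = 5.0,
                per_core: bool = False) -> pd.DataFrame:
    """Add trimmed z-score columns (``z_<marker>``) for every marker.

    z = (MFI - mean) / sd with the sample sd (n-1 denominator), computed
    per marker over all retained cells (or within each core when
    ``per_core`` is set, for sensitivity analysis), then clamped to
    [-clip, +clip].  The number of clamped values is logged.
    """
    out = table.copy()
    markers = marker_columns(table)

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        x = block.to_numpy(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        bad = np.flatnonzero(~(sd > 0))
        if bad.size:
            names = [markers[i] for i in bad]
            raise ValueError(f"zero-variance marker(s): {names}")
        return pd.DataFrame((x - mu) / sd, index=block.index, columns=markers)

    if per_core:
        z = pd.concat(
            [_z(g[markers]) for _, g in table.groupby("core_id", sort=False)]
        ).loc[table.index]
    else:
        z = _z(table[markers])

    n_clipped = int((np.abs(z.to_numpy()) > clip).sum())
    if n_clipped:
        logger.info("zscore_trim: clamped %d values to +/-%g", n_clipped, clip)
    z = z.clip(-clip, clip)
    for m in markers:
        out[Z_PREFIX + m] = z[m].to_numpy()
    return out


def pearson_marker_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Marker-by-marker Pearson correlation matrix over all cells."""
    if len(table) < 2:
        raise ValueError("need at least 2 cells for a correlation matrix")
    markers = marker_columns(table)
    return table[markers].corr(method="pearson")


def run_qc(table: pd.DataFrame, min_expressed_markers: int = 3,
           min_fraction: float = 0.01, clip: float = 5.0,
           expression_threshold: float = 0.0,
           per_core: bool = False) -> pd.DataFrame:
    """Full QC chain: cell filter, marker filter, trimmed z-scores."""
    table = filter_cells(table, min_expressed_markers, expression_threshold)
    table = filter_markers(table, min_fraction, expression_threshold)
    return zscore_trim(table, clip=clip, per_core=per_core)
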