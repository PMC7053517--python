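"""Signature-based cell-type assignment and activation signatures for
external RNA validation.

Single cells are assigned to immune cell types by Spearman correlation
against signature mean-expression profiles (e.g. the LM22 22-type
matrix): over the genes shared between the expression matrix and the
signatures, each cell takes the type of its best-correlating profile,
and cells whose maximum correlation falls below a cutoff (default 0.25)
stay unassigned.  Because Spearman works on ranks, the assignment is
invariant to any strictly monotone transform of a cell's expression
vector (log, CPM scaling, ...).

CD8+ T cells identified this way can be split into Active/Exhausted with
the imaging-derived activation model applied to the transcripts encoding
CD69, OX40, LAG3 and TIM3; averaging those cells' expression yields two
new signature profiles usable for bulk deconvolution.  Patients are
labelled Active when their Active CD8 fraction is at least the Exhausted
fraction.

The default transcript list for the four markers is a best guess
(notably OX40 = TNFRSF4, TIM3 = HAVCR2) and is NOT authoritative; pass
your own ``genes``/``gene_to_marker`` mapping for serious use.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import activation as _activation
from .panel import ACTIVATION_MARKERS

logger = logging.getLogger(__name__)

#: Best-guess transcript ids for the four activation/exhaustion proteins
#: (non-authoritative; override via function arguments).
DEFAULT_ACTIVATION_GENES: tuple[str, ...] = (
    "CD69", "TNFRSF4", "TNFSF4", "LAG3", "HAVCR2", "LGALS9",
)
DEFAULT_GENE_TO_MARKER: dict[str, str] = {
    "CD69": "CD69",
    "TNFRSF4": "OX40",
    "TNFSF4": "OX40",
    "LAG3": "LAG3",
    "HAVCR2": "TIM3",
    "LGALS9": "TIM3",
}


def _normalize_genes(index) -> pd.Index:
    return pd.Index([str(g).upper() for g in index])


def load_signature_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a signature matrix TSV (gene-symbol column + one column per
    cell type, LM22 layout)."""
    sig = pd.read_csv(path, sep=sep, index_col=0)
    sig.index = _normalize_genes(sig.index)
    return validate_signatures(sig)


def validate_signatures(signatures: pd.DataFrame) -> pd.DataFrame:
    if signatures.index.duplicated().any():
        raise ValueError("duplicate gene ids in signature matrix")
    if signatures.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell types")
    return signatures


def assign_cell_types(
    expr: pd.DataFrame,
    signatures: pd.DataFrame,
    cutoff: float = 0.25,
) -> pd.DataFrame:
    """Correlation-based cell-type assignment.

    Parameters
    ----------
    expr
        cells x genes expression frame (columns = gene symbols).
    signatures
        genes x cell-types mean-expression profiles.
    cutoff
        Cells whose best Spearman correlation is below this value stay
        ``unassigned``.

    Returns a frame indexed like ``expr`` with columns cell_type and
    max_correlation.
    """
    signatures = validate_signatures(signatures)
    expr = expr.copy()
    expr.columns = _normalize_genes(expr.columns)
    sig_genes = _normalize_genes(signatures.index)
    shared = expr.columns.intersection(sig_genes)
    if len(shared) == 0:
        raise ValueError("no genes shared between expression and signatures")
    logger.info("assign_cell_types: %d shared genes", len(shared))
    X = expr[shared].to_numpy(float)
    S = signatures.set_axis(sig_genes).loc[shared].to_numpy(float)

    # Spearman = Pearson on ranks (average ranks for ties)
    Xr = np.apply_along_axis(rankdata, 1, X)
    Sr = np.apply_along_axis(rankdata, 0, S)
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    Sc = Sr - Sr.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ss = np.sqrt((Sc**2).sum(axis=0))
    zero_var = xs == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} cell(s) with zero-variance expression; "
            "unassigned",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc @ Sc) / np.outer(xs, ss)
    rho = np.where(np.isfinite(rho), rho, -np.inf)
    best = rho.argmax(axis=1)
    best_rho = rho[np.arange(len(rho)), best]
    types = signatures.columns.to_numpy()[best].astype(object)
    types[(best_rho < cutoff) | zero_var] = "unassigned"
    return pd.DataFrame(
        {"cell_type": types,
         "max_correlation": np.where(np.isfinite(best_rho), best_rho, np.nan)},
        index=expr.index,
    )


def score_cd8_expression(
    cd8_expr: pd.DataFrame,
    genes: tuple[str, ...] = DEFAULT_ACTIVATION_GENES,
    gene_to_marker: dict[str, str] | None = None,
) -> np.ndarray:
    """Activation scores for CD8 cells from transcript expression.

    The listed transcripts are z-scored, averaged into the four marker
    channels (CD69, OX40, LAG3, TIM3), and run through the PCA activation
    model.
    """
    if gene_to_marker is None:
        gene_to_marker = DEFAULT_GENE_TO_MARKER
    expr = cd8_expr.copy()
    expr.columns = _normalize_genes(expr.columns)
    genes_u = [g.upper() for g in genes]
    missing = [g for g in genes_u if g not in expr.columns]
    if missing:
        raise ValueError(f"activation genes absent from expression: {missing}")
    sub = expr[genes_u].to_numpy(float)
    sd = sub.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [genes_u[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance activation gene(s): {bad}")
    z = (sub - sub.mean(axis=0)) / sd
    channels = np.zeros((len(expr), 4))
    g2m = {k.upper(): v for k, v in gene_to_marker.items()}
    for mi, marker in enumerate(ACTIVATION_MARKERS):
        cols = [i for i, g in enumerate(genes_u) if g2m.get(g) == marker]
        if not cols:
            raise ValueError(f"no transcript mapped to marker {marker}")
        channels[:, mi] = z[:, cols].mean(axis=1)
    model = _activation.fit_activation_model(channels)
    return _activation.score_cells(model, channels)


def build_activation_signatures(
    cd8_expr: pd.DataFrame,
    genes: tuple[str, ...] = DEFAULT_ACTIVATION_GENES,
    gene_to_marker: dict[str, str] | None = None,
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Active/Exhausted CD8 signature profiles over the activation genes.

    Cells with activation > 0 form the Active class, the rest (score
    exactly 0 included) the Exhausted class; profiles are the per-gene
    mean expression of each class.  Raises when either class is empty.
    """
    expr = cd8_expr.copy()
    expr.columns = _normalize_genes(expr.columns)
    genes_u = [g.upper() for g in genes]
    if scores is None:
        scores = score_cd8_expression(cd8_expr, genes, gene_to_marker)
    scores = np.asarray(scores, float)
    active = scores > 0
    if not active.any() or active.all():
        raise ValueError(
            "one activation class is empty; cannot build both signatures"
        )
    prof = pd.DataFrame(
        {
            "T.cells.CD8.Active": expr.loc[active, genes_u].mean(axis=0),
            "T.cells.CD8.Exhausted": expr.loc[~active, genes_u].mean(axis=0),
        }
    )
    prof.index.name = "gene"
    return prof


def label_patients(fractions: pd.DataFrame) -> pd.Series:
    """Active/Exhausted patient labels from deconvolved CD8 fractions.

    ``fractions`` needs columns active and exhausted (per-patient CD8
    subtype proportions); a patient is Active when the Active fraction
    is greater than or equal to the Exhausted one.  Rows with missing
    fractions are skipped with a log entry.
    """
    required = {"active", "exhausted"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    ok = fractions[["active", "exhausted"]].notna().all(axis=1)
    if (~ok).any():
        logger.warning("%d patient(s) with missing fractions skipped",
                       int((~ok).sum()))
    sub = fractions.loc[ok]
    if ((sub["active"] < 0) | (sub["exhausted"] < 0)).any():
        raise ValueError("fractions must be non-negative")
    return pd.Series(
        np.where(sub["active"] >= sub["exhausted"], "Active", "Exhausted"),
        index=sub.index,
        name="label",
    )
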