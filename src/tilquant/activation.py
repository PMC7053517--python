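"""PCA-based activation/exhaustion scoring of CD8+ T cells.

The four functional markers CD69, OX40 (activation) and LAG3, TIM3
(exhaustion) are measured as trimmed z-scores on CD8+ cells.  A PCA of
this 4-column matrix typically yields a first component on which all four
markers load with the same sign — a common-mode "overall staining" axis —
so the functional structure lives in the PC2-PC3 plane.  In that plane the
direction of the CD69 loading defines maximum activation (score +1) and
the direction of the TIM3 loading defines maximum exhaustion (score -1);
every cell is scored by where the direction of its centred projection
falls along the angular gradient between those two anchors, with the
centroid of the projected data as the neutral origin (score 0).  LAG3 and
OX40 shape the PCA fit but do not define anchors: LAG3's loading is not
aligned with TIM3's and few cells express it, so it contributes little to
the exhaustion end of the gradient.

Scores depend only on the *direction* of a cell's projection, not its
distance from the centroid: a weakly and a strongly stained cell pointing
the same way get the same score.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import ACTIVATION_MARKERS

logger = logging.getLogger(__name__)

_IDX_CD69 = ACTIVATION_MARKERS.index("CD69")
_IDX_TIM3 = ACTIVATION_MARKERS.index("TIM3")


class CommonModeWarning(UserWarning):
    """PC1 is not a common-mode axis; component selection fell back."""


@dataclass
class ActivationModel:
    """Fitted activation-gradient model.

    Attributes
    ----------
    rotation
        Full 4x4 PCA loading matrix (columns = components), after sign
        fixing.
    component_indices
        The two retained components (0-based; default (1, 2) = PC2, PC3).
    mean
        Per-marker mean of the training z-scores (PCA centering).
    centroid
        Centroid of the training projections in the retained plane.
    anchor_active, anchor_exhausted
        Unit vectors in the retained plane: the CD69 and TIM3 loading
        directions.
    """

    rotation: np.ndarray
    component_indices: tuple[int, int]
    mean: np.ndarray
    centroid: np.ndarray
    anchor_active: np.ndarray
    anchor_exhausted: np.ndarray
    marker_order: tuple[str, ...] = ACTIVATION_MARKERS
    explained_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("anchor_active", "anchor_exhausted"):
            v = np.asarray(getattr(self, name), float)
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError(f"{name} must be unit length")
        ang = angle_between(self.anchor_active, self.anchor_exhausted)
        if ang < 1e-6:
            raise ValueError("anchors are collinear; gradient undefined")
        if self.component_indices[0] == self.component_indices[1]:
            raise ValueError("component_indices must be distinct")

    # ---- persistence ---------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "rotation": self.rotation.tolist(),
            "component_indices": list(self.component_indices),
            "mean": self.mean.tolist(),
            "centroid": self.centroid.tolist(),
            "anchor_active": self.anchor_active.tolist(),
            "anchor_exhausted": self.anchor_exhausted.tolist(),
            "marker_order": list(self.marker_order),
            "explained_variance": self.explained_variance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ActivationModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            rotation=np.asarray(doc["rotation"], float),
            component_indices=tuple(doc["component_indices"]),
            mean=np.asarray(doc["mean"], float),
            centroid=np.asarray(doc["centroid"], float),
            anchor_active=np.asarray(doc["anchor_active"], float),
            anchor_exhausted=np.asarray(doc["anchor_exhausted"], float),
            marker_order=tuple(doc["marker_order"]),
            explained_variance=np.asarray(doc["explained_variance"], float),
        )


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two 2-vectors, in [0, pi].

    atan2 formulation: accurate near 0 and pi, where arccos loses half
    the floating-point digits."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.arctan2(abs(cross), dot))


def fit_activation_model(cd8_z: np.ndarray) -> ActivationModel:
    """Fit the PCA activation model on CD8+ cells.

    Parameters
    ----------
    cd8_z
        n x 4 matrix of z-scores with columns (CD69, OX40, LAG3, TIM3).

    Returns
    -------
    ActivationModel with PC2/PC3 retained when PC1 is common-mode (all
    four PC1 loadings share one sign); otherwise the pair of components
    that maximally separates CD69 from TIM3 in angle is retained and a
    :class:`CommonModeWarning` is emitted.
    """
    X = np.asarray(cd8_z, float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("expected an n x 4 matrix (CD69, OX40, LAG3, TIM3)")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 CD8+ cells to fit the model")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [ACTIVATION_MARKERS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}; PCA is rank-deficient")

    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD-based PCA; V rows are components
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    rotation = Vt.T  # markers x components, columns are loadings
    var = (Xc @ rotation).var(axis=0, ddof=1)

    pc1 = rotation[:, 0]
    common_mode = np.all(pc1 > 0) or np.all(pc1 < 0)
    if common_mode:
        comps = (1, 2)
    else:
        comps = _fallback_components(rotation)
        warnings.warn(
            "PC1 loadings do not share a sign; retaining components "
            f"{comps[0] + 1} and {comps[1] + 1} (maximal CD69/TIM3 angular "
            "separation) instead of PC2/PC3",
            CommonModeWarning,
            stacklevel=2,
        )

    rotation = _fix_signs(rotation, comps)
    plane = rotation[:, comps]                    # 4 x 2
    proj = Xc @ plane                             # n x 2
    centroid = proj.mean(axis=0)

    a = plane[_IDX_CD69]
    e = plane[_IDX_TIM3]
    anchor_active = a / np.linalg.norm(a)
    anchor_exhausted = e / np.linalg.norm(e)

    return ActivationModel(
        rotation=rotation,
        component_indices=comps,
        mean=mean,
        centroid=centroid,
        anchor_active=anchor_active,
        anchor_exhausted=anchor_exhausted,
        explained_variance=var,
    )


def _fallback_components(rotation: np.ndarray) -> tuple[int, int]:
    """Component pair maximising the CD69-TIM3 angle in the induced plane."""
    best, best_ang = (1, 2), -1.0
    for i in range(4):
        for j in range(i + 1, 4):
            a = rotation[_IDX_CD69, [i, j]]
            e = rotation[_IDX_TIM3, [i, j]]
            if np.linalg.norm(a) < 1e-12 or np.linalg.norm(e) < 1e-12:
                continue
            ang = angle_between(a, e)
            if ang > best_ang:
                best, best_ang = (i, j), ang
    return best


def _fix_signs(rotation: np.ndarray, comps: tuple[int, int]) -> np.ndarray:
    """Resolve PCA sign indeterminacy deterministically: the first retained
    component is flipped so CD69 loads positively on it, the second so TIM3
    loads non-negatively on it."""
    rotation = rotation.copy()
    c0, c1 = comps
    if rotation[_IDX_CD69, c0] < 0:
        rotation[:, c0] *= -1
    if rotation[_IDX_TIM3, c1] < 0:
        rotation[:, c1] *= -1
    return rotation


def project_cells(model: ActivationModel, cd8_z: np.ndarray) -> np.ndarray:
    """Centred projection of cells into the retained plane (centroid at 0)."""
    X = np.asarray(cd8_z, float)
    if X.ndim != 2 or X.shape[1] != len(model.marker_order):
        raise ValueError(
            f"expected an n x {len(model.marker_order)} matrix in marker "
            f"order {model.marker_order}"
        )
    plane = model.rotation[:, model.component_indices]
    return (X - model.mean) @ plane - model.centroid


def score_cells(model: ActivationModel, cd8_z: np.ndarray,
                strategy: str = "angular") -> np.ndarray:
    """Score cells along the activation gradient; values in [-1, 1].

    ``angular`` (default): with phi_a and phi_e the angles between a cell's
    centred projection and the active/exhausted anchors, and Delta the
    angle between the anchors, the score is (phi_e - phi_a) / Delta.  This
    is linear in angle along the shorter arc between the anchors (+1 at
    the CD69 anchor, -1 at the TIM3 anchor, 0 on the bisector) and is
    bounded in [-1, 1] everywhere by the triangle inequality for angles.

    ``projection``: signed projection of the cell's direction onto the
    normalized anchor-difference axis, rescaled so the anchors map to
    +/-1, then clamped.

    Cells exactly at the centroid score 0.
    """
    v = project_cells(model, cd8_z)
    r = np.linalg.norm(v, axis=1)
    a, e = model.anchor_active, model.anchor_exhausted
    scores = np.zeros(len(v))
    ok = r > 1e-12
    if strategy == "angular":
        delta = angle_between(a, e)
        vh = v[ok] / r[ok, None]
        # atan2-based angles stay accurate for cells near the anchors
        phi_a = np.arctan2(
            np.abs(vh[:, 0] * a[1] - vh[:, 1] * a[0]), vh @ a
        )
        phi_e = np.arctan2(
            np.abs(vh[:, 0] * e[1] - vh[:, 1] * e[0]), vh @ e
        )
        scores[ok] = (phi_e - phi_a) / delta
    elif strategy == "projection":
        u = a - e
        u = u / np.linalg.norm(u)
        scale = float(a @ u)  # == -e @ u by symmetry of unit anchors
        vh = v[ok] / r[ok, None]
        scores[ok] = (vh @ u) / scale
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return np.clip(scores, -1.0, 1.0)


def score_table(table, model: ActivationModel | None = None,
                phenotype_column: str = "phenotype", cd8_label: str = "Tcy",
                strategy: str = "angular"):
    """Fit (if needed) and score the CD8+ cells of a cell table.

    Adds/overwrites an ``activation`` column (NaN for non-CD8 cells) and
    returns ``(table, model)``.
    """
    from .panel import z_cols

    table = table.copy()
    mask = table[phenotype_column] == cd8_label
    if not mask.any():
        raise ValueError(f"no cells labelled {cd8_label!r}")
    Z = table.loc[mask, z_cols(ACTIVATION_MARKERS)].to_numpy(float)
    if model is None:
        model = fit_activation_model(Z)
    table["activation"] = np.nan
    table.loc[mask, "activation"] = score_cells(model, Z, strategy=strategy)
    return table, model
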