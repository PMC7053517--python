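"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes, at the
scale of a melanoma tissue-microarray study (by default 29 patients,
1-4 cores each for ~60 cores, thousands of cells per core):

* per-phenotype marker intensities: every marker has a positive baseline
  intensity, lineage-defining markers are elevated, and all values carry
  multiplicative log-normal noise (MFIs are non-negative and
  right-skewed);
* a planted activation gradient on cytotoxic T cells: each Tcy cell gets
  a functional class (active / transition / exhausted / anergic) with
  class-specific CD69, OX40, LAG3, TIM3 means, mixed per core according
  to the core's planted status;
* spatial point patterns: uniform (complete spatial randomness)
  background with optional planted pairwise attraction (satellite
  placement within a radius) or avoidance (rejection sampling outside a
  radius);
* a per-patient clinical table with exponential overall-survival times
  whose scale depends on the planted patient status.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PANEL

#: Defining (high) markers per phenotype; all other markers sit at baseline.
PHENOTYPE_PROFILES: dict[str, tuple[str, ...]] = {
    "Melanoma": ("S100AB", "MelanA"),
    "Macroph": ("CD68", "Lysozyme", "CD163", "HLA-DR"),
    "Tcy": ("CD3", "CD8"),
    "Th": ("CD3", "CD4"),
    "Treg": ("CD3", "CD4", "FOXP3"),
    "Tfh": ("CXCL13", "PD-1"),
    "BC": ("CD20",),
    "PC": ("IRF4", "Blimp1", "CD138"),
    "NK": ("CD56", "CD16"),
    "cDC1": ("CD141", "IRF8"),
    "cDC2": ("CD1c", "HLA-DR"),
    "Lang": ("CD1a", "Langerin"),
    "pDC": ("CD123",),
    "LV": ("Podoplanin",),
}

#: Default cohort composition (fractions sum to 1).
DEFAULT_PROPORTIONS: dict[str, float] = {
    "Melanoma": 0.40, "Macroph": 0.12, "Tcy": 0.12, "Th": 0.10,
    "Treg": 0.03, "Tfh": 0.03, "BC": 0.02, "PC": 0.02, "NK": 0.02,
    "cDC1": 0.04, "cDC2": 0.03, "Lang": 0.02, "pDC": 0.01, "LV": 0.04,
}

#: Planted functional-class means for the four scored markers on Tcy cells.
FUNCTIONAL_CLASS_MEANS: dict[str, dict[str, float]] = {
    "active":     {"CD69": 8.0, "OX40": 6.0, "LAG3": 1.0, "TIM3": 1.0},
    "transition": {"CD69": 4.0, "OX40": 3.0, "LAG3": 2.0, "TIM3": 4.0},
    "exhausted":  {"CD69": 1.0, "OX40": 1.0, "LAG3": 3.0, "TIM3": 8.0},
    "anergic":    {"CD69": 1.0, "OX40": 1.0, "LAG3": 1.0, "TIM3": 1.0},
}

#: Core-status -> (active, transition, exhausted, anergic) Tcy fractions.
DEFAULT_STATUS_MIXES: dict[str, tuple[float, float, float, float]] = {
    "Active":     (0.70, 0.15, 0.05, 0.10),
    "Transition": (0.15, 0.55, 0.15, 0.15),
    "Exhausted":  (0.05, 0.15, 0.70, 0.10),
}

FUNCTIONAL_CLASSES = ("active", "transition", "exhausted", "anergic")

BASELINE_INTENSITY = 1.0
HIGH_INTENSITY = 8.0


@dataclass
class SyntheticConfig:
    """Study-design parameters for a synthetic cohort."""

    n_patients: int = 29
    cores_per_patient: tuple[int, int] = (1, 4)
    cells_per_core: tuple[int, int] = (3000, 5000)
    field_size: tuple[float, float] = (2000.0, 2000.0)
    phenotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    marker_means: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.4
    # sd (log scale) of the per-cell common staining/size factor shared by
    # all markers; strong enough that the first principal component of the
    # four scored markers is common-mode (all loadings one sign), as in
    # real MFI data where cells stain brighter or dimmer as a whole
    cell_factor_sd: float = 0.8
    activation_mix: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_MIXES)
    )
    core_statuses: list[str] | None = None  # planted per-core; None -> cycle
    interaction_spec: list[tuple[str, str, str, float]] = field(
        default_factory=list
    )
    interaction_radius: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phenotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype proportions sum to {total!r}, expected 1"
            )
        if any(v < 0 for v in self.phenotype_proportions.values()):
            raise ValueError("phenotype proportions must be non-negative")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if any(v < 0 for v in self.marker_means.values()):
            raise ValueError("marker intensities must be non-negative")
        for status, mix in self.activation_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9 or any(f < 0 for f in mix):
                raise ValueError(f"invalid activation mix for {status!r}")
        for spec in self.interaction_spec:
            if spec[2] not in ("attraction", "avoidance", "none"):
                raise ValueError(f"unknown interaction mode {spec[2]!r}")

    def mean_for(self, phenotype: str, marker: str) -> float:
        if (phenotype, marker) in self.marker_means:
            return self.marker_means[(phenotype, marker)]
        if marker in PHENOTYPE_PROFILES.get(phenotype, ()):
            return HIGH_INTENSITY
        return BASELINE_INTENSITY


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated cohort."""

    cells: pd.DataFrame          # cell_id, phenotype, functional_class
    core_status: dict[str, str]  # core_id -> planted status
    patient_status: dict[str, str]
    interactions: list[tuple[str, str, str, float]]


def generate_spatial_pattern(
    n_by_type: dict[str, int],
    interaction_spec: list[tuple[str, str, str, float]],
    field_size: tuple[float, float],
    radius: float,
    seed=None,
    max_attempts: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Point pattern with planted pairwise attraction/avoidance.

    Types never appearing as the second member of an interaction are
    placed uniformly (complete spatial randomness).  For
    ("i", "j", "attraction", s) a fraction ``s`` of type-j cells is
    placed uniformly within ``radius`` of a random type-i cell; for
    avoidance a fraction ``s`` is rejection-sampled outside ``radius`` of
    every type-i cell (``max_attempts`` tries per cell before erroring).
    Returns (positions n x 2, labels n).
    """
    from scipy.spatial import cKDTree

    w, h = field_size
    if radius >= min(w, h) / 2:
        raise ValueError("radius must be smaller than half the field size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    spec_by_j: dict[str, tuple[str, str, float]] = {}
    for i, j, mode, strength in interaction_spec:
        if mode != "none" and j not in spec_by_j:
            spec_by_j[j] = (i, mode, float(strength))

    pos: dict[str, np.ndarray] = {}
    order = [t for t in n_by_type if t not in spec_by_j] + [
        t for t in n_by_type if t in spec_by_j
    ]
    for t in order:
        n = int(n_by_type[t])
        if t not in spec_by_j:
            pos[t] = rng.uniform((0, 0), (w, h), size=(n, 2))
            continue
        anchor_type, mode, strength = spec_by_j[t]
        anchors = pos.get(anchor_type)
        if anchors is None or len(anchors) == 0:
            raise ValueError(
                f"interaction for {t!r} references missing type {anchor_type!r}"
            )
        n_coupled = int(round(strength * n))
        pts = np.empty((n, 2))
        pts[n_coupled:] = rng.uniform((0, 0), (w, h), size=(n - n_coupled, 2))
        if mode == "attraction":
            for k in range(n_coupled):
                centre = anchors[rng.integers(len(anchors))]
                for _ in range(max_attempts):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = radius * math.sqrt(rng.uniform())
                    p = centre + rad * np.array([math.cos(ang), math.sin(ang)])
                    if 0 <= p[0] <= w and 0 <= p[1] <= h:
                        pts[k] = p
                        break
                else:
                    raise RuntimeError(
                        "could not place an attracted cell inside the field"
                    )
        else:  # avoidance
            tree = cKDTree(anchors)
            for k in range(n_coupled):
                for _ in range(max_attempts):
                    p = rng.uniform((0, 0), (w, h))
                    if tree.query(p, k=1)[0] > radius:
                        pts[k] = p
                        break
                else:
                    raise RuntimeError(
                        "rejection sampling failed: field too crowded for "
                        "the requested avoidance pattern"
                    )
        pos[t] = pts

    positions = np.vstack([pos[t] for t in n_by_type])
    labels = np.concatenate(
        [np.full(int(n_by_type[t]), t, dtype=object) for t in n_by_type]
    )
    return positions, labels


def _draw_mfi(rng: np.random.Generator, mean: float, sigma: float,
              size: int) -> np.ndarray:
    """Multiplicative positive noise around a target mean intensity."""
    return mean * rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate (cell table, ground truth) for a whole cohort.

    The cell table has cell_id, patient_id, core_id, x, y and one raw-MFI
    column per panel marker; the truth records every cell's planted
    phenotype and (for Tcy) functional class, plus per-core and
    per-patient planted statuses.
    """
    rng = np.random.default_rng(config.seed)
    phenos = list(config.phenotype_proportions)
    probs = np.array([config.phenotype_proportions[p] for p in phenos])
    statuses = list(config.activation_mix)

    cells_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    core_status: dict[str, str] = {}
    patient_status: dict[str, str] = {}

    core_counter = 0
    for p_idx in range(config.n_patients):
        patient_id = f"P{p_idx + 1:02d}"
        lo, hi = config.cores_per_patient
        n_cores = int(rng.integers(lo, hi + 1))
        patient_core_statuses = []
        for _ in range(n_cores):
            core_id = f"C{core_counter + 1:03d}"
            if config.core_statuses is not None:
                status = config.core_statuses[core_counter]
            else:
                status = statuses[core_counter % len(statuses)]
            core_counter += 1
            core_status[core_id] = status
            patient_core_statuses.append(status)

            n_cells = int(rng.integers(config.cells_per_core[0],
                                       config.cells_per_core[1] + 1))
            cell_phenos = rng.choice(phenos, size=n_cells, p=probs)
            counts = pd.Series(cell_phenos).value_counts().to_dict()
            if config.interaction_spec:
                positions, labels = generate_spatial_pattern(
                    counts, config.interaction_spec, config.field_size,
                    config.interaction_radius, seed=rng,
                )
                cell_phenos = labels
            else:
                positions = rng.uniform(
                    (0, 0), config.field_size, size=(n_cells, 2)
                )

            # marker intensities per phenotype block
            mfi = np.empty((n_cells, len(PANEL)))
            for pheno in counts:
                mask = cell_phenos == pheno
                k = int(mask.sum())
                for mi, marker in enumerate(PANEL):
                    mfi[mask, mi] = _draw_mfi(
                        rng, config.mean_for(pheno, marker),
                        config.noise_sd, k,
                    )

            # planted functional classes on Tcy cells
            functional = np.full(n_cells, "", dtype=object)
            tcy = np.flatnonzero(cell_phenos == "Tcy")
            if tcy.size:
                mix = np.asarray(config.activation_mix[status], float)
                classes = rng.choice(FUNCTIONAL_CLASSES, size=tcy.size, p=mix)
                functional[tcy] = classes
                for cls in FUNCTIONAL_CLASSES:
                    idx = tcy[classes == cls]
                    if idx.size == 0:
                        continue
                    for marker, mean in FUNCTIONAL_CLASS_MEANS[cls].items():
                        mi = PANEL.index(marker)
                        mfi[idx, mi] = _draw_mfi(
                            rng, mean, config.noise_sd, idx.size
                        )

            if config.cell_factor_sd > 0:
                s = config.cell_factor_sd
                factor = rng.lognormal(-(s**2) / 2, s, size=n_cells)
                mfi *= factor[:, None]

            cell_ids = [
                f"{core_id}_{i + 1:05d}" for i in range(n_cells)
            ]
            block = pd.DataFrame(mfi, columns=list(PANEL))
            block.insert(0, "y", positions[:, 1])
            block.insert(0, "x", positions[:, 0])
            block.insert(0, "core_id", core_id)
            block.insert(0, "patient_id", patient_id)
            block.insert(0, "cell_id", cell_ids)
            cells_rows.append(block)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "phenotype": cell_phenos,
                        "functional_class": functional,
                        "core_status": status,
                    }
                )
            )
        # patient planted status: majority of its cores (ties -> Transition)
        vc = pd.Series(patient_core_statuses).value_counts()
        if len(vc) == 1 or vc.iloc[0] > vc.iloc[1]:
            patient_status[patient_id] = vc.index[0]
        else:
            patient_status[patient_id] = "Transition"

    cells = pd.concat(cells_rows, ignore_index=True)
    truth = SyntheticTruth(
        cells=pd.concat(truth_rows, ignore_index=True),
        core_status=core_status,
        patient_status=patient_status,
        interactions=list(config.interaction_spec),
    )
    return cells, truth


#: Overall-survival scale (arbitrary time units) per planted status.
_OS_SCALE = {"Active": 80.0, "Transition": 50.0, "Exhausted": 30.0}


def generate_clinical(truth: SyntheticTruth, seed: int = 0,
                      censor_time: float = 120.0) -> pd.DataFrame:
    """Per-patient clinical table with status-dependent survival."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid, status in truth.patient_status.items():
        t = rng.exponential(_OS_SCALE[status])
        event = int(t <= censor_time)
        rows.append(
            {"patient_id": pid, "os_time": min(t, censor_time),
             "os_event": event}
        )
    return pd.DataFrame(rows)


def reduced_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Small-profile config for tests and desk-scale runs
    (10 patients x 1 core, <=1000 cells/core by default)."""
    kw = dict(
        n_patients=10,
        cores_per_patient=(1, 1),
        cells_per_core=(600, 1000),
        field_size=(1200.0, 1200.0),
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)
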