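"""Active / Transition / Exhausted classification of cores and patients.

Each analysis unit (a TMA core, or all cells of a patient pooled across
cores) is compared against the background distribution of activation
scores (all scored cells of the cohort, the unit's own cells included)
with two one-tailed two-sample t-tests: unit mean greater than background
(the Active side) and unit mean smaller than background (the Exhausted
side).  Raw p-values are collected across all units and adjusted with the
Benjamini-Hochberg FDR procedure, separately per side by default.  A unit
is Active when its adjusted Active-side p is below alpha (default 0.001),
Exhausted when the Exhausted side is, and Transition otherwise.

The module also provides the subsampling robustness analysis (how many
cells are needed to reproduce a patient's classification) and the
dichotomized Kaplan-Meier / log-rank survival comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ACTIVE, TRANSITION, EXHAUSTED = "Active", "Transition", "Exhausted"


@dataclass
class StatusCall:
    unit_id: object
    status: str
    n_cells: int
    mean_activation: float
    p_active_adj: float
    p_exhausted_adj: float


@dataclass
class RobustnessCurve:
    patient_id: object
    sample_sizes: np.ndarray
    consistency: np.ndarray
    min_n_95: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_size": self.sample_sizes, "consistency": self.consistency}
        )


def _side_pvalues(unit: np.ndarray, background: np.ndarray,
                  equal_var: bool = False) -> tuple[float, float]:
    """One-tailed (active-side, exhausted-side) p-values, Welch by default."""
    p_act = stats.ttest_ind(
        unit, background, equal_var=equal_var, alternative="greater"
    ).pvalue
    p_exh = stats.ttest_ind(
        unit, background, equal_var=equal_var, alternative="less"
    ).pvalue
    return float(p_act), float(p_exh)


def _label(p_act: float, p_exh: float, alpha: float) -> str:
    if p_act < alpha and p_exh < alpha:  # impossible for one-tailed pairs; guarded
        logger.warning("both sides significant; calling Transition")
        return TRANSITION
    if p_act < alpha:
        return ACTIVE
    if p_exh < alpha:
        return EXHAUSTED
    return TRANSITION


def classify_units(
    groups: dict[object, np.ndarray],
    background: np.ndarray,
    alpha: float = 0.001,
    equal_var: bool = False,
    fdr_family: str = "per-side",
) -> list[StatusCall]:
    """Classify several units jointly (FDR adjustment across units).

    Parameters
    ----------
    groups
        unit_id -> activation scores of that unit's cells.
    background
        Activation scores of the whole cohort.
    fdr_family
        "per-side" (default): BH applied separately to the Active-side and
        Exhausted-side p-value families; "joint": one BH over both.
    """
    background = np.asarray(background, float)
    if background.size < 2:
        raise ValueError("background needs at least 2 cells")
    ids, p_act, p_exh, ns, means = [], [], [], [], []
    for uid, vals in groups.items():
        vals = np.asarray(vals, float)
        if vals.size < 2:
            logger.warning("unit %r has <2 cells; excluded as unclassifiable", uid)
            continue
        pa, pe = _side_pvalues(vals, background, equal_var=equal_var)
        ids.append(uid)
        p_act.append(pa)
        p_exh.append(pe)
        ns.append(vals.size)
        means.append(float(vals.mean()))
    if not ids:
        return []
    p_act, p_exh = np.array(p_act), np.array(p_exh)
    if fdr_family == "per-side":
        p_act_adj = multipletests(p_act, method="fdr_bh")[1]
        p_exh_adj = multipletests(p_exh, method="fdr_bh")[1]
    elif fdr_family == "joint":
        adj = multipletests(np.concatenate([p_act, p_exh]), method="fdr_bh")[1]
        p_act_adj, p_exh_adj = adj[: len(ids)], adj[len(ids):]
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return [
        StatusCall(uid, _label(pa, pe, alpha), n, m, float(pa), float(pe))
        for uid, pa, pe, n, m in zip(ids, p_act_adj, p_exh_adj, ns, means)
    ]


def _scores_by(table: pd.DataFrame, key: str) -> tuple[dict, np.ndarray]:
    scored = table.dropna(subset=["activation"])
    if scored.empty:
        raise ValueError("no scored cells; run activation scoring first")
    groups = {
        uid: g["activation"].to_numpy(float)
        for uid, g in scored.groupby(key, sort=False)
    }
    return groups, scored["activation"].to_numpy(float)


def classify_cores(table: pd.DataFrame, alpha: float = 0.001,
                   equal_var: bool = False,
                   fdr_family: str = "per-side") -> list[StatusCall]:
    """One StatusCall per core, FDR-adjusted across all cores jointly."""
    groups, background = _scores_by(table, "core_id")
    return classify_units(groups, background, alpha, equal_var, fdr_family)


def classify_patients(table: pd.DataFrame, alpha: float = 0.001,
                      equal_var: bool = False,
                      fdr_family: str = "per-side") -> list[StatusCall]:
    """Pool each patient's cells across cores, then classify as for cores."""
    groups, background = _scores_by(table, "patient_id")
    return classify_units(groups, background, alpha, equal_var, fdr_family)


def classify_one(values: np.ndarray, background: np.ndarray,
                 alpha: float = 0.001, equal_var: bool = False) -> str:
    """Classify a single unit (no multiplicity adjustment beyond itself)."""
    pa, pe = _side_pvalues(np.asarray(values, float), background, equal_var)
    return _label(pa, pe, alpha)


def robustness_resample(
    patient_scores: np.ndarray,
    background: np.ndarray,
    full_label: str,
    sizes: np.ndarray | None = None,
    reps: int = 100,
    alpha: float = 0.001,
    seed: int | None = None,
    equal_var: bool = False,
) -> RobustnessCurve:
    """Reclassification consistency under subsampling.

    For each sample size, ``reps`` subsamples are drawn without
    replacement (capped at the patient's cell count) and reclassified
    against the full background; consistency is the fraction matching the
    full-data label.  ``min_n_95`` is the smallest size whose consistency
    reaches 0.95.
    """
    patient_scores = np.asarray(patient_scores, float)
    background = np.asarray(background, float)
    if sizes is None:
        sizes = np.arange(10, 1001, 10)
    sizes = np.asarray(sizes, int)
    rng = np.random.default_rng(seed)
    consistency = np.empty(len(sizes))
    for i, size in enumerate(sizes):
        k = min(int(size), patient_scores.size)
        hits = 0
        for _ in range(reps):
            sub = rng.choice(patient_scores, size=k, replace=False)
            if classify_one(sub, background, alpha, equal_var) == full_label:
                hits += 1
        consistency[i] = hits / reps
    reached = np.flatnonzero(consistency >= 0.95)
    min_n = int(sizes[reached[0]]) if reached.size else None
    return RobustnessCurve(None, sizes, consistency, min_n)


def dichotomize_patients(table: pd.DataFrame) -> pd.DataFrame:
    """Mean activation per patient, dichotomized: Active if mean > 0,
    Exhausted otherwise (mean exactly 0 counts as Exhausted)."""
    scored = table.dropna(subset=["activation"])
    means = scored.groupby("patient_id")["activation"].mean()
    return pd.DataFrame(
        {
            "patient_id": means.index,
            "mean_activation": means.to_numpy(),
            "group": np.where(means.to_numpy() > 0, ACTIVE, EXHAUSTED),
        }
    ).reset_index(drop=True)


def dichotomize_and_logrank(table: pd.DataFrame,
                            clinical: pd.DataFrame) -> dict:
    """Kaplan-Meier comparison of Active vs Exhausted patients.

    ``clinical`` must carry patient_id, os_time and os_event columns.
    Returns the log-rank statistic/p-value and the fitted KM estimators.
    """
    groups = dichotomize_patients(table).merge(clinical, on="patient_id")
    fitters = {}
    for name, g in groups.groupby("group"):
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(g["os_time"], event_observed=g["os_event"])
        fitters[name] = kmf
    if len(fitters) < 2:
        raise ValueError("one dichotomized group is empty; log-rank undefined")
    a = groups[groups["group"] == ACTIVE]
    e = groups[groups["group"] == EXHAUSTED]
    res = logrank_test(
        a["os_time"], e["os_time"], a["os_event"], e["os_event"]
    )
    return {
        "groups": groups,
        "km": fitters,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
    }


def status_frame(calls: list[StatusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [c.unit_id for c in calls],
            "status": [c.status for c in calls],
            "n_cells": [c.n_cells for c in calls],
            "mean_activation": [c.mean_activation for c in calls],
            "p_active_adj": [c.p_active_adj for c in calls],
            "p_exhausted_adj": [c.p_exhausted_adj for c in calls],
        }
    )
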