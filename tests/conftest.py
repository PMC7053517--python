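"""Shared fixtures: synthetic cohorts at test scale.

Tests run on generated data with planted ground truth so every stage can
be checked against known answers without any external download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tilquant as tq
from tilquant.synthetic import (
    SyntheticConfig,
    generate_cohort,
    reduced_config,
)


@pytest.fixture(scope="session")
def reduced_cohort():
    """Small default-profile cohort (10 cores) with truth."""
    cfg = reduced_config(seed=11)
    cells, truth = generate_cohort(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def scored_cohort(reduced_cohort):
    """Reduced cohort after QC + activation scoring.

    Planted phenotypes stand in for the consensus call so the scoring and
    status modules are tested in isolation from the clustering.
    """
    _, cells, truth = reduced_cohort
    norm = tq.run_qc(cells)
    norm = norm.merge(truth.cells[["cell_id", "phenotype"]], on="cell_id")
    scored, model = tq.activation.score_table(norm)
    return scored, model, truth


@pytest.fixture(scope="session")
def separated_cohort():
    """Five well-separated phenotypes, one core of 5000 cells, minimal
    brightness confounding — the regime where consensus phenotyping is
    expected to recover the planted partition."""
    props = {"Tcy": 0.2, "Th": 0.2, "BC": 0.2, "Macroph": 0.2, "Melanoma": 0.2}
    cfg = SyntheticConfig(
        n_patients=1,
        cores_per_patient=(1, 1),
        cells_per_core=(5000, 5000),
        phenotype_proportions=props,
        cell_factor_sd=0.15,
        seed=7,
    )
    cells, truth = generate_cohort(cfg)
    return cfg, cells, truth


def make_cell_table(mfi: np.ndarray, markers: list[str],
                    core_id: str = "C1", patient_id: str = "P1") -> pd.DataFrame:
    """Tiny hand-built cell table for unit tests."""
    n = len(mfi)
    df = pd.DataFrame(np.asarray(mfi, float), columns=markers)
    df.insert(0, "y", np.zeros(n))
    df.insert(0, "x", np.arange(n, dtype=float))
    df.insert(0, "core_id", core_id)
    df.insert(0, "patient_id", patient_id)
    df.insert(0, "cell_id", [f"{core_id}_{i}" for i in range(n)])
    return df
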