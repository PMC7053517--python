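"""Cohort-level statistics linking activation to histopathology.

Each core's activation is summarised by the mean score of its CD8+ cells
(with the sd capturing intra-core heterogeneity).  Categorical
histopathological factors with two levels are tested with a two-sample
t-test; factors with more than two levels with all pairwise pooled-sd
t-tests, Holm-adjusted; continuous covariates (Breslow thickness,
lymphocyte count) with the slope test of an ordinary linear model.
Cellular-composition differences between core groups use rank tests
(Wilcoxon rank-sum for two groups, Kruskal-Wallis for three or more).

The qPCR rule classifies micro-dissected TIL samples from expression
relative to CD45: ``active`` when log(IFNg/CD45) > 0, ``exhausted`` when
LAG3 and/or TIM3 are expressed while IFNg and CD40L are not.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def pooled_sd_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test with pooled standard deviation (equal-variance).

    Returns (t, two-sided p)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=True)
    return float(res.statistic), float(res.pvalue)


def core_activation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of the activation score per core."""
    scored = table.dropna(subset=["activation"])
    g = scored.groupby("core_id")["activation"]
    return pd.DataFrame(
        {"core_id": g.mean().index, "mean": g.mean().to_numpy(),
         "sd": g.std(ddof=1).to_numpy(), "n": g.size().to_numpy()}
    )


def activation_vs_factor(
    core_means: pd.DataFrame,
    covariates: pd.DataFrame,
    factor: str,
    kind: str = "categorical",
    min_cores: int = 2,
) -> pd.DataFrame:
    """Test per-core mean activation against one histopathological factor.

    ``core_means`` needs core_id and mean columns; ``covariates`` carries
    core_id plus the factor column.  Categorical factors: two levels give
    a plain two-sample t-test (no correction); more levels give all
    pairwise pooled-sd t-tests with Holm adjustment.  Continuous factors:
    linear-model slope test.
    """
    df = core_means.merge(covariates[["core_id", factor]], on="core_id").dropna(
        subset=[factor]
    )
    if kind == "continuous":
        res = stats.linregress(df[factor].to_numpy(float), df["mean"].to_numpy(float))
        return pd.DataFrame(
            [{
                "factor": factor, "comparison": f"{factor} vs activation",
                "test": "linear model", "corrected": False,
                "statistic": float(res.slope / res.stderr),
                "p_value": float(res.pvalue), "p_adj": float(res.pvalue),
            }]
        )
    levels = []
    for lev, g in df.groupby(factor):
        if len(g) < min_cores:
            logger.warning("level %r has <%d cores; excluded", lev, min_cores)
            continue
        levels.append((lev, g["mean"].to_numpy(float)))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has <2 usable levels")
    rows = []
    if len(levels) == 2:
        (la, xa), (lb, xb) = levels
        t, p = pooled_sd_ttest(xa, xb)
        rows.append(
            {"factor": factor, "comparison": f"{la} vs {lb}", "test": "t test",
             "corrected": False, "statistic": t, "p_value": p, "p_adj": p}
        )
    else:
        pvals = []
        for (la, xa), (lb, xb) in itertools.combinations(levels, 2):
            t, p = pooled_sd_ttest(xa, xb)
            rows.append(
                {"factor": factor, "comparison": f"{la} vs {lb}",
                 "test": "pairwise t test", "corrected": True,
                 "statistic": t, "p_value": p}
            )
            pvals.append(p)
        adj = multipletests(pvals, method="holm")[1]
        for r, pa in zip(rows, adj):
            r["p_adj"] = float(pa)
    return pd.DataFrame(rows)


def statistics_table(
    core_means: pd.DataFrame,
    covariates: pd.DataFrame,
    factors: dict[str, str],
) -> pd.DataFrame:
    """Run :func:`activation_vs_factor` for several factors.

    ``factors`` maps column name -> "categorical" or "continuous"."""
    frames = [
        activation_vs_factor(core_means, covariates, f, kind)
        for f, kind in factors.items()
    ]
    return pd.concat(frames, ignore_index=True)


def composition_tests(
    fractions: pd.DataFrame,
    grouping: pd.Series | dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subpopulation composition tests across core groups.

    ``fractions``: cores x subpopulations frame of per-core cell-fraction
    values (index = core_id).  ``grouping``: core_id -> group label.  Two
    groups use the Wilcoxon rank-sum (Mann-Whitney) test, three or more
    Kruskal-Wallis; constant fractions give p = 1 with a warning.
    """
    groups = pd.Series(grouping)
    common = fractions.index.intersection(groups.index)
    fractions = fractions.loc[common]
    groups = groups.loc[common]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for sub in fractions.columns:
        samples = [
            fractions.loc[groups == lab, sub].to_numpy(float) for lab in labels
        ]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            warnings.warn(f"constant fractions for {sub!r}; p = 1", stacklevel=2)
            stat, p = 0.0, 1.0
            test = "constant"
        elif len(labels) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
            stat, p, test = float(res.statistic), float(res.pvalue), "wilcoxon"
        else:
            res = stats.kruskal(*samples)
            stat, p, test = float(res.statistic), float(res.pvalue), "kruskal"
        rows.append(
            {"subpopulation": sub, "test": test, "statistic": stat,
             "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def core_composition(table: pd.DataFrame,
                     label_column: str = "phenotype") -> pd.DataFrame:
    """Cores x subpopulations fraction matrix from a labelled cell table."""
    counts = (
        table.groupby(["core_id", label_column], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def qpcr_classify(samples: pd.DataFrame,
                  expression_floor: float = 0.0) -> pd.DataFrame:
    """Classify micro-dissected samples from qPCR expression values.

    Requires columns sample_id, IFNg, TIM3, LAG3, CD40L, CD45.  A sample
    is ``active`` when log(IFNg/CD45) is strictly positive; ``exhausted``
    when LAG3 and/or TIM3 are expressed (above ``expression_floor``)
    while IFNg and CD40L are not; ``neither`` otherwise.
    """
    required = {"sample_id", "IFNg", "TIM3", "LAG3", "CD40L", "CD45"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (samples["CD45"] <= 0).any():
        raise ValueError("CD45 expression must be positive for the ratio")
    with np.errstate(divide="ignore"):  # IFNg = 0 -> logFC = -inf, valid
        logfc = np.log(samples["IFNg"].to_numpy(float) /
                       samples["CD45"].to_numpy(float))
    expressed = lambda col: samples[col].to_numpy(float) > expression_floor
    active = logfc > 0
    exhausted = (
        (expressed("LAG3") | expressed("TIM3"))
        & ~expressed("IFNg")
        & ~expressed("CD40L")
    )
    label = np.where(active, "active",
                     np.where(exhausted, "exhausted", "neither"))
    return pd.DataFrame(
        {"sample_id": samples["sample_id"], "log_ifng_cd45": logfc,
         "label": label}
    )
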