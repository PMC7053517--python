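"""Clustering methods, rulebook annotation, consensus, functional tiers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import tilquant as tq
from tilquant import phenotyping as ph
from tilquant.panel import FUNCTIONAL_MARKERS, PHENOTYPIC_MARKERS
from tilquant.rules import Rule, Rulebook, UNASSIGNED


def three_blobs(n_per=100, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
    X = np.vstack([c + rng.normal(0, 0.5, (n_per, 2)) for c in centers])
    truth = np.repeat([0, 1, 2], n_per)
    return X, truth


class TestClusteringMethods:
    @pytest.mark.parametrize("method", ph.METHODS)
    def test_three_blobs_recovered(self, method):
        # for graph clustering on tiny data, k must be on the order of the
        # smallest subpopulation, else modularity over-splits
        X, truth = three_blobs()
        labels = ph.cluster_three_ways(
            X, seed=0, kmeans_k=3, knn=45, dp_clusters=3
        )[method]
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_duplicate_rows_get_identical_labels(self):
        X, _ = three_blobs(n_per=50)
        X = np.vstack([X, X[:5]])
        for method, labels in ph.cluster_three_ways(
            X, seed=0, kmeans_k=3, knn=10, dp_clusters=3
        ).items():
            assert np.array_equal(labels[:5], labels[150:]), method

    def test_same_seed_reruns_identically(self):
        X, _ = three_blobs(seed=3)
        a = ph.cluster_three_ways(X, seed=42, kmeans_k=3, knn=15, dp_clusters=3)
        b = ph.cluster_three_ways(X, seed=42, kmeans_k=3, knn=15, dp_clusters=3)
        for method in ph.METHODS:
            assert np.array_equal(a[method], b[method]), method

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            ph.cluster_three_ways(np.zeros((1, 2)), seed=0)


class TestAnnotation:
    @pytest.fixture()
    def rulebook(self):
        return tq.default_phenotype_rulebook()

    @staticmethod
    def _mean(high=(), extra=None):
        m = {mk: -0.3 for mk in PHENOTYPIC_MARKERS}
        for mk in high:
            m[mk] = 2.0
        if extra:
            m.update(extra)
        return m

    def test_cd3_cd8_high_is_tcy(self, rulebook):
        assert rulebook.assign(self._mean(("CD3", "CD8"))) == "Tcy"

    def test_cd3_cd4_foxp3_high_is_treg(self, rulebook):
        assert rulebook.assign(self._mean(("CD3", "CD4", "FOXP3"))) == "Treg"

    def test_all_means_near_zero_unassigned(self, rulebook):
        m = {mk: 0.0 for mk in PHENOTYPIC_MARKERS}
        assert rulebook.assign(m) == UNASSIGNED

    def test_unique_priorities_enforced(self):
        with pytest.raises(ValueError, match="priorities"):
            Rulebook(rules=[Rule("A", ("CD3",), priority=1),
                            Rule("B", ("CD8",), priority=1)])

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            Rulebook(rules=[Rule("A", ("NOPE",), priority=0)])

    def test_empty_rulebook_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            Rulebook(rules=[])

    def test_yaml_round_trip(self, tmp_path, rulebook):
        path = tmp_path / "rules.yaml"
        rulebook.to_yaml(path)
        loaded = Rulebook.from_yaml(path)
        assert loaded.rules == rulebook.rules
        assert loaded.hi_threshold == rulebook.hi_threshold

    def test_stricter_thresholds_assign_fewer(self, rulebook):
        mean = self._mean(("CD3", "CD8"), extra={"CD3": 0.8, "CD8": 0.8})
        assert rulebook.assign(mean) == "Tcy"
        strict = Rulebook(rules=list(rulebook.rules), hi_threshold=1.0)
        assert strict.assign(mean) == UNASSIGNED


class TestConsensus:
    def test_unanimous_kept(self):
        out = ph.consensus_assign(
            {"a": ["Th"], "b": ["Th"], "c": ["Th"]}
        )
        assert out[0] == "Th"

    def test_two_of_three_majority_wins(self):
        out = ph.consensus_assign(
            {"a": ["Th"], "b": ["Th"], "c": ["Tcy"]}
        )
        assert out[0] == "Th"

    def test_three_way_disagreement_discarded(self):
        out = ph.consensus_assign(
            {"a": ["Th"], "b": ["Tcy"], "c": ["BC"]}
        )
        assert out[0] == ph.DISCARDED

    def test_unassigned_majority_is_discarded(self):
        out = ph.consensus_assign(
            {"a": [UNASSIGNED], "b": [UNASSIGNED], "c": ["Th"]}
        )
        assert out[0] == ph.DISCARDED

    def test_consensus_only_from_proposed_labels(self):
        rng = np.random.default_rng(0)
        opts = np.array(["Th", "Tcy", "BC", UNASSIGNED], dtype=object)
        votes = {m: rng.choice(opts, 300) for m in ("a", "b", "c")}
        out = ph.consensus_assign(votes)
        for i, lab in enumerate(out):
            if lab != ph.DISCARDED:
                assert lab in {votes[m][i] for m in votes}

    def test_wrong_method_count_errors(self):
        with pytest.raises(ValueError):
            ph.consensus_assign({"a": ["Th"], "b": ["Th"]})


class TestEndToEnd:
    def test_separated_cohort_recovery(self, separated_cohort):
        """Well-separated planted phenotypes are recovered by the
        consensus (>=90% of cells), disagreements discarded."""
        _, cells, truth = separated_cohort
        norm = tq.run_qc(cells)
        pheno, report = tq.phenotype_cells(
            norm, tq.default_phenotype_rulebook(), seed=0,
            kmeans_range=(4, 8),
        )
        merged = pheno.merge(
            truth.cells[["cell_id", "phenotype"]],
            on="cell_id", suffixes=("", "_true"),
        )
        assert (merged["phenotype"] == merged["phenotype_true"]).mean() >= 0.90
        assert report["inclusion_fraction"] >= 0.90


class TestFunctionalSubcluster:
    @pytest.fixture()
    def functional_rulebook(self):
        return tq.default_functional_rulebook()

    @staticmethod
    def _fmean(values):
        m = {mk: -0.3 for mk in FUNCTIONAL_MARKERS}
        m.update(values)
        return m

    def test_lag3_tim3_high_cd69_ox40_low_is_exhausted(self, functional_rulebook):
        mean = self._fmean({"LAG3": 1.5, "TIM3": 2.0, "CD69": -0.5, "OX40": -0.5})
        assert functional_rulebook.assign(mean) == "exhausted"

    def test_lag3_only_still_exhausted(self, functional_rulebook):
        mean = self._fmean({"LAG3": 1.5, "TIM3": -0.3, "CD69": -0.5, "OX40": -0.5})
        assert functional_rulebook.assign(mean) == "exhausted"

    def test_all_functional_means_near_zero_is_anergic(self, functional_rulebook):
        mean = self._fmean({mk: 0.0 for mk in FUNCTIONAL_MARKERS})
        assert functional_rulebook.assign(mean) == "anergic"

    def test_cd69_high_tim3_low_is_active(self, functional_rulebook):
        mean = self._fmean({"CD69": 1.5, "OX40": 0.8, "TIM3": -0.4, "LAG3": -0.4})
        assert functional_rulebook.assign(mean) == "active"

    def test_planted_subtypes_recovered(self):
        """Tcy functional subclustering separates planted active from
        exhausted cells (ARI > 0.9 on the two-class subset) when the
        brightness confounder is mild."""
        from tilquant.synthetic import generate_cohort, reduced_config

        cfg = reduced_config(seed=21, n_patients=3, cell_factor_sd=0.25)
        cells, truth = generate_cohort(cfg)
        norm = tq.run_qc(cells)
        scored = norm.merge(truth.cells[["cell_id", "phenotype"]], on="cell_id")
        sub = tq.functional_subcluster(
            scored, tq.default_functional_rulebook(), seed=0
        )
        merged = sub[sub["phenotype"] == "Tcy"].merge(
            truth.cells[["cell_id", "functional_class"]], on="cell_id"
        )
        two = merged[merged["functional_class"].isin(["active", "exhausted"])]
        assert adjusted_rand_score(
            two["functional_class"], two["functional_label"].astype(str)
        ) > 0.9

    def test_tiny_phenotype_single_cluster_warning(self, functional_rulebook):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.normal(0, 1, (5, len(FUNCTIONAL_MARKERS))),
            columns=[f"z_{m}" for m in FUNCTIONAL_MARKERS],
        )
        table["phenotype"] = "Th"
        table["cell_id"] = [f"c{i}" for i in range(5)]
        with pytest.warns(UserWarning, match="single functional cluster"):
            out = tq.functional_subcluster(table, functional_rulebook, seed=0)
        assert out["functional_label"].nunique() == 1
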