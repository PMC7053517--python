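"""Core/patient status calls, robustness resampling, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tilquant as tq
from tilquant import status as st


def uniform_background(n=2000, seed=0):
    return np.random.default_rng(seed).uniform(-1, 1, n)


class TestClassifyUnits:
    def test_unit_of_plus_ones_is_active(self):
        bg = uniform_background()
        calls = st.classify_units({"u": np.ones(200)}, bg)
        assert calls[0].status == "Active"
        # oracle: Welch t is astronomically significant
        t = sps.ttest_ind(np.ones(200), bg, equal_var=False,
                          alternative="greater")
        assert t.pvalue < 1e-100

    def test_unit_of_minus_ones_is_exhausted(self):
        bg = uniform_background()
        calls = st.classify_units({"u": -np.ones(200)}, bg)
        assert calls[0].status == "Exhausted"

    def test_iid_sample_of_background_is_transition(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(-1, 1, 5000)
        unit = rng.choice(bg, 100, replace=False)
        calls = st.classify_units({"u": unit}, bg, alpha=0.001)
        assert calls[0].status == "Transition"

    def test_tiny_unit_excluded(self):
        calls = st.classify_units(
            {"tiny": np.array([1.0]), "ok": np.zeros(50)}, uniform_background()
        )
        assert [c.unit_id for c in calls] == ["ok"]

    def test_exactly_one_label_per_unit(self, scored_cohort):
        scored, _, _ = scored_cohort
        calls = tq.classify_cores(scored)
        assert len(calls) == scored["core_id"].nunique()
        assert all(c.status in ("Active", "Transition", "Exhausted")
                   for c in calls)


class TestClassifyCoresAndPatients:
    def test_planted_statuses_recovered(self, scored_cohort):
        scored, _, truth = scored_cohort
        df = st.status_frame(tq.classify_cores(scored))
        df["truth"] = df["unit_id"].map(truth.core_status)
        assert (df["status"] == df["truth"]).mean() >= 0.95

    def test_single_core_dataset_is_transition(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {"core_id": "C1", "patient_id": "P1",
             "activation": rng.uniform(-1, 1, 100)}
        )
        calls = tq.classify_cores(table)
        assert calls[0].status == "Transition"

    def test_identical_score_distributions_get_identical_labels(self):
        vals = np.linspace(-0.2, 0.9, 80)
        table = pd.DataFrame(
            {"core_id": ["C1"] * 80 + ["C2"] * 80,
             "patient_id": "P1",
             "activation": np.concatenate([vals, vals])}
        )
        calls = tq.classify_cores(table)
        assert calls[0].status == calls[1].status
        assert calls[0].p_active_adj == pytest.approx(calls[1].p_active_adj)

    def test_patient_with_one_core_matches_core_status(self, scored_cohort):
        scored, _, _ = scored_cohort
        cores = st.status_frame(tq.classify_cores(scored))
        patients = st.status_frame(tq.classify_patients(scored))
        core_per_patient = scored.groupby("patient_id")["core_id"].nunique()
        for pid in core_per_patient[core_per_patient == 1].index:
            cid = scored.loc[scored["patient_id"] == pid, "core_id"].iloc[0]
            assert (
                patients.set_index("unit_id").loc[pid, "status"]
                == cores.set_index("unit_id").loc[cid, "status"]
            )

    def test_balanced_opposite_cores_pool_to_transition(self):
        # symmetric Active and Exhausted cores cancel at the patient level
        a = np.full(150, 0.8) + np.linspace(-0.05, 0.05, 150)
        e = -a
        table = pd.DataFrame(
            {"core_id": ["C1"] * 150 + ["C2"] * 150,
             "patient_id": "P1",
             "activation": np.concatenate([a, e])}
        )
        patients = tq.classify_patients(table)
        assert patients[0].status == "Transition"

    def test_patient_call_invariant_to_core_boundaries(self, scored_cohort):
        scored, _, _ = scored_cohort
        before = st.status_frame(tq.classify_patients(scored))
        shuffled = scored.copy()
        rng = np.random.default_rng(3)
        shuffled["core_id"] = rng.permutation(shuffled["core_id"].to_numpy())
        after = st.status_frame(tq.classify_patients(shuffled))
        pd.testing.assert_frame_equal(
            before.sort_values("unit_id").reset_index(drop=True),
            after.sort_values("unit_id").reset_index(drop=True),
        )

    def test_null_cohort_false_call_rate_controlled(self):
        """Cores drawn i.i.d. from the background: non-Transition calls
        stay near the FDR target (simulation at reduced size)."""
        rng = np.random.default_rng(4)
        false_calls = total = 0
        for _ in range(1000):
            scores = rng.uniform(-1, 1, 500)
            cores = np.repeat(np.arange(10), 50)
            groups = {c: scores[cores == c] for c in range(10)}
            calls = st.classify_units(groups, scores, alpha=0.001)
            false_calls += sum(c.status != "Transition" for c in calls)
            total += len(calls)
        assert false_calls / total <= 0.005


class TestRobustness:
    def test_degenerate_patient_fully_consistent(self):
        bg = np.concatenate([np.ones(1200), uniform_background()])
        curve = st.robustness_resample(
            np.ones(1200), bg, "Active", reps=100, seed=0
        )
        assert (curve.consistency == 1.0).all()
        assert curve.min_n_95 == 10

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        mine = rng.uniform(0, 1, 400)
        bg = np.concatenate([mine, rng.uniform(-1, 1, 2000)])
        kw = dict(sizes=np.arange(10, 210, 10), reps=30, alpha=0.001, seed=9)
        c1 = st.robustness_resample(mine, bg, "Active", **kw)
        c2 = st.robustness_resample(mine, bg, "Active", **kw)
        np.testing.assert_array_equal(c1.consistency, c2.consistency)

    def test_strong_separation_needs_few_cells(self):
        """A strongly Active synthetic patient reaches 95% consistency
        with at most 100 cells."""
        rng = np.random.default_rng(6)
        mine = rng.normal(0.8, 0.15, 1000).clip(-1, 1)
        bg = np.concatenate([mine, rng.uniform(-1, 1, 4000)])
        full = st.classify_one(mine, bg)
        assert full == "Active"
        curve = st.robustness_resample(mine, bg, full, reps=100, seed=1)
        assert curve.min_n_95 is not None and curve.min_n_95 <= 100


class TestSurvival:
    @staticmethod
    def _table(means):
        rows = []
        for pid, m in means.items():
            rows.append(
                pd.DataFrame(
                    {"patient_id": pid, "core_id": pid,
                     "activation": np.full(20, m)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_mean_zero_goes_to_exhausted_group(self):
        groups = st.dichotomize_patients(self._table({"P1": 0.0, "P2": 0.4}))
        assert groups.set_index("patient_id").loc["P1", "group"] == "Exhausted"
        assert groups.set_index("patient_id").loc["P2", "group"] == "Active"

    def test_identical_survival_gives_p_one(self):
        table = self._table({"P1": 0.5, "P2": 0.5, "P3": -0.5, "P4": -0.5})
        clinical = pd.DataFrame(
            {"patient_id": ["P1", "P2", "P3", "P4"],
             "os_time": [5.0, 9.0, 5.0, 9.0],
             "os_event": [1, 1, 1, 1]}
        )
        res = st.dichotomize_and_logrank(table, clinical)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_logrank_matches_hand_computed_statistic(self):
        # deaths only in the Active group at t=1,2; Exhausted censored at 5,6
        # O-E = 1/2 + 2/3 = 7/6 ; V = 1/4 + 2/9 = 17/36 ; chi2 = 49/17
        table = self._table({"P1": 0.5, "P2": 0.5, "P3": -0.5, "P4": -0.5})
        clinical = pd.DataFrame(
            {"patient_id": ["P1", "P2", "P3", "P4"],
             "os_time": [1.0, 2.0, 5.0, 6.0],
             "os_event": [1, 1, 0, 0]}
        )
        res = st.dichotomize_and_logrank(table, clinical)
        assert res["statistic"] == pytest.approx(49 / 17, abs=1e-10)
        assert res["p_value"] == pytest.approx(
            float(sps.chi2.sf(49 / 17, 1)), abs=1e-10
        )

    def test_single_group_errors(self):
        table = self._table({"P1": 0.5, "P2": 0.6})
        clinical = pd.DataFrame(
            {"patient_id": ["P1", "P2"], "os_time": [1.0, 2.0],
             "os_event": [1, 1]}
        )
        with pytest.raises(ValueError, match="empty"):
            st.dichotomize_and_logrank(table, clinical)
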