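"""Signature scoring, coverage, agreement, clustering, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slideproteo import normalize, signatures
from slideproteo.errors import DefinitionError, InsufficientDataError
from slideproteo.io import SignatureDefinition
from slideproteo.simulate import SimConfig, simulate_cohort, simulate_two_instruments


class TestSignatureScore:
    def test_mean_of_scaled_values(self):
        scaled = pd.DataFrame({"S1": [1.0, 3.0], "S2": [0.0, -2.0]}, index=["A", "B"])
        out = signatures.signature_score(scaled, SignatureDefinition("sig", ("A", "B")))
        assert dict(zip(out["sample_id"], out["score"])) == {"S1": 2.0, "S2": -1.0}
        assert (out["n_used"] == 2).all()

    def test_absent_signature_scores_missing(self):
        scaled = pd.DataFrame({"S1": [1.0]}, index=["A"])
        out = signatures.signature_score(scaled, SignatureDefinition("sig", ("X", "Y")))
        assert out["score"].isna().all()

    def test_min_coverage_guard(self):
        scaled = pd.DataFrame({"S1": [1.0]}, index=["A"])
        sig = SignatureDefinition("sig", ("A", "X", "Y", "Z"))
        assert signatures.signature_score(scaled, sig, min_coverage=0.5)["score"].isna().all()
        assert (
            signatures.signature_score(scaled, sig, min_coverage=0.25)["score"] == 1.0
        ).all()

    def test_tis_score_recovers_immune_fraction(self, cohort68, sigs):
        scaled = normalize.scale_per_protein(
            normalize.median_normalize_log2(cohort68.quant_imputed)
        )
        score = signatures.signature_score(scaled, sigs["TIS"]).set_index("sample_id")["score"]
        rho = stats.spearmanr(score, cohort68.truth.samples["immune_fraction"]).statistic
        assert rho >= 0.8


class TestHistologyScore:
    def test_hand_arithmetic(self):
        # AC markers average 8, SCC markers average 2 on the linear scale
        norm = pd.DataFrame(
            {"S1": np.log2([8.0, 8.0, 2.0, 2.0])}, index=["NKX2-1", "NAPSA", "TP63", "DSG3"]
        )
        ac = SignatureDefinition("AC", ("NKX2-1", "NAPSA"))
        scc = SignatureDefinition("SCC", ("TP63", "DSG3"))
        out = signatures.histology_score(norm, ac, scc)
        np.testing.assert_allclose(out["S1"], 2.0)
        # equal class means -> 0; swapping the panels flips the sign
        np.testing.assert_allclose(
            signatures.histology_score(norm, ac, ac)["S1"], 0.0, atol=1e-12
        )
        np.testing.assert_allclose(
            signatures.histology_score(norm, scc, ac)["S1"], -2.0
        )

    def test_absent_class_rejected(self):
        norm = pd.DataFrame({"S1": [1.0]}, index=["NKX2-1"])
        with pytest.raises(DefinitionError, match="SCC"):
            signatures.histology_score(
                norm,
                SignatureDefinition("AC", ("NKX2-1",)),
                SignatureDefinition("SCC", ("TP63",)),
            )

    def test_separates_simulated_histologies(self, sigs):
        c = simulate_cohort(SimConfig(n_samples=60, seed=11))
        norm = normalize.median_normalize_log2(c.quant_imputed)
        score = signatures.histology_score(norm, sigs["AC_MARKERS"], sigs["SCC_MARKERS"])
        histo = c.truth.samples["histology"]
        p = stats.mannwhitneyu(
            score[histo == "AC"].dropna(), score[histo == "SCC"].dropna()
        ).pvalue
        assert score[histo == "AC"].median() > score[histo == "SCC"].median()
        assert p < 0.01


class TestListCoverage:
    def test_three_of_four(self):
        mat = pd.DataFrame({"S1": [1.0, np.nan, 3.0], "S2": [np.nan, 2.0, np.nan]},
                           index=["A", "B", "C"])
        pct, per_sample = signatures.list_coverage(mat, SignatureDefinition("L", ("A", "B", "C", "D")))
        assert pct == 75.0
        assert per_sample["S1"] == 50.0 and per_sample["S2"] == 25.0

    def test_empty_overlap(self):
        mat = pd.DataFrame({"S1": [1.0]}, index=["A"])
        pct, per = signatures.list_coverage(mat, SignatureDefinition("L", ("X", "Y")))
        assert pct == 0.0 and (per == 0.0).all()

    def test_monotone_as_samples_added(self, small_cohort, sigs):
        mat = small_cohort.quant
        panel = sigs["LUNG_ACTIONABLE_MARKERS_SYNTHETIC"]
        prev = 0.0
        for k in range(1, mat.shape[1] + 1):
            pct, _ = signatures.list_coverage(mat.iloc[:, :k], panel)
            assert pct >= prev - 1e-12
            prev = pct

    def test_matches_set_oracle(self, small_cohort, sigs):
        panel = sigs["TIS"]
        pct, _ = signatures.list_coverage(small_cohort.quant, panel)
        identified = {
            p for p in small_cohort.quant.index
            if small_cohort.quant.loc[p].notna().any()
        }
        oracle = 100.0 * len(set(panel.genes) & identified) / len(panel.genes)
        assert pct == oracle


class TestCrossDatasetAgreement:
    @staticmethod
    def _scores(vals, ids):
        return pd.DataFrame({"sample_id": ids, "signature": "TIS", "score": vals})

    def test_identical_and_reversed(self):
        ids = [f"S{i}" for i in range(6)]
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rho, n, _ = signatures.cross_dataset_agreement(self._scores(vals, ids), self._scores(vals, ids))
        assert rho == 1.0 and n == 6
        rho, _, _ = signatures.cross_dataset_agreement(
            self._scores(vals, ids), self._scores(vals[::-1], ids)
        )
        assert rho == -1.0

    def test_too_few_common(self):
        with pytest.raises(InsufficientDataError):
            signatures.cross_dataset_agreement(
                self._scores([1, 2, 3], ["A", "B", "C"]), self._scores([1, 2, 3], ["A", "B", "X"])
            )

    def test_two_instruments_agree_on_tis(self, sigs):
        both = simulate_two_instruments(SimConfig(n_samples=40, seed=17))
        scores = {}
        for instr, cohort in both.items():
            scaled = normalize.scale_per_protein(
                normalize.median_normalize_log2(cohort.quant_imputed)
            )
            scores[instr] = signatures.signature_score(scaled, sigs["TIS"])
        rho, n, _ = signatures.cross_dataset_agreement(scores["astral"], scores["timstof"])
        assert n == 40 and rho >= 0.6


class TestClustering:
    def test_identical_profiles_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        scaled = pd.DataFrame(
            [base, base, rng.normal(size=10)], index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(10)],
        )
        order, link = signatures.cluster_signature_rows(
            scaled, SignatureDefinition("sig", ("A", "B", "C"))
        )
        assert set(order) == {"A", "B", "C"}
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}  # A,B merge first
        np.testing.assert_allclose(link[0, 2], 0.0, atol=1e-12)

    def test_correlated_pair_merges_before_anticorrelated(self):
        t = np.linspace(0, 1, 12)
        scaled = pd.DataFrame(
            [t, t + 0.01 * np.sin(20 * t), -t], index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(12)],
        )
        _, link = signatures.cluster_signature_rows(
            scaled, SignatureDefinition("sig", ("A", "B", "C"))
        )
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_constant_profile_placed_last(self, caplog):
        rng = np.random.default_rng(1)
        scaled = pd.DataFrame(
            [rng.normal(size=8), rng.normal(size=8), np.ones(8)],
            index=["A", "B", "FLAT"], columns=[f"S{i}" for i in range(8)],
        )
        with caplog.at_level("WARNING"):
            order, _ = signatures.cluster_signature_rows(
                scaled, SignatureDefinition("sig", ("A", "B", "FLAT"))
            )
        assert order[-1] == "FLAT"


class TestGroupCompare:
    def test_identical_groups(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        stat, p = signatures.group_compare(vals, groups, "welch")
        assert stat == 0.0 and p > 0.99

    def test_strong_separation(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        for test in ("welch", "wilcoxon"):
            assert signatures.group_compare(vals, groups, test)[1] < 1e-6

    def test_welch_matches_hand_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 12)
        vals = pd.Series(np.concatenate([a, b]))
        groups = pd.Series(["a"] * 15 + ["b"] * 12)
        stat, p = signatures.group_compare(vals, groups, "welch")
        va, vb = a.var(ddof=1) / 15, b.var(ddof=1) / 12
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 14 + vb**2 / 11)
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        np.testing.assert_allclose(stat, t_hand, rtol=1e-10)
        np.testing.assert_allclose(p, p_hand, rtol=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            signatures.group_compare(
                pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"])
            )
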