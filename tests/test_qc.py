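"""QC metrics: arithmetic oracles, fence rules, concordance properties."""

import numpy as np
import pandas as pd
import pytest

from slideproteo import qc
from slideproteo.errors import (
    DefinitionError,
    InsufficientDataError,
    SampleLookupError,
    UndefinedMetricError,
)
from slideproteo.io import SignatureDefinition

KER = SignatureDefinition("K", ("KRT1",))


def _prec(rows):
    return pd.DataFrame(rows, columns=["sample_id", "protein", "peptide_id", "ms1_area"])


class TestIdCount:
    def test_counts_non_missing(self):
        mat = pd.DataFrame(
            {"S1": [1.0, np.nan, 3.0, 4.0, np.nan], "S2": [np.nan] * 5},
            index=list("ABCDE"),
        )
        assert qc.id_count(mat, "S1") == 3
        assert qc.id_count(mat, "S2") == 0
        with pytest.raises(SampleLookupError):
            qc.id_count(mat, "S9")

    def test_matches_brute_force(self, small_cohort):
        counts = qc.id_counts(small_cohort.quant)
        for sid in small_cohort.quant.columns:
            brute = sum(
                1 for v in small_cohort.quant[sid].to_numpy() if np.isfinite(v)
            )
            assert counts[sid] == brute


class TestSignalFraction:
    def test_all_signal_from_set(self):
        t = _prec([("S1", "KRT1", "p1", 500.0)])
        assert qc.signal_fraction(t, "S1", KER) == 1.0

    def test_no_member_detected(self):
        t = _prec([("S1", "ALB", "p1", 500.0)])
        assert qc.signal_fraction(t, "S1", KER) == 0.0

    def test_mixed_arithmetic(self):
        t = _prec([("S1", "KRT1", "p1", 300.0), ("S1", "ALB", "p2", 700.0)])
        np.testing.assert_allclose(qc.signal_fraction(t, "S1", KER), 0.30)

    def test_vectorized_matches_scalar(self, small_cohort, sigs):
        fracs = qc.signal_fractions(small_cohort.precursors, sigs["SKIN_KERATINS"])
        for sid in fracs.index[:4]:
            np.testing.assert_allclose(
                fracs[sid],
                qc.signal_fraction(small_cohort.precursors, sid, sigs["SKIN_KERATINS"]),
            )
        assert fracs.between(0, 1).all()


class TestTopNFraction:
    def test_single_protein(self):
        t = _prec([("S1", "ALB", "p1", 5.0)])
        assert qc.top_n_fraction(t, "S1", 20) == 1.0

    def test_forty_equal_proteins(self):
        t = _prec([("S1", f"P{i:02d}", f"p{i}", 10.0) for i in range(40)])
        np.testing.assert_allclose(qc.top_n_fraction(t, "S1", 20), 0.5)

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(1)
        areas = rng.lognormal(5, 2, 100)
        t = _prec([("S1", f"P{i:03d}", f"p{i}", a) for i, a in enumerate(areas)])
        expect = np.sort(areas)[::-1][:20].sum() / areas.sum()
        np.testing.assert_allclose(qc.top_n_fraction(t, "S1", 20), expect, rtol=1e-12)

    def test_monotone_in_n(self):
        rng = np.random.default_rng(2)
        t = _prec([("S1", f"P{i}", f"p{i}", v) for i, v in enumerate(rng.lognormal(0, 1, 30))])
        fracs = [qc.top_n_fraction(t, "S1", n) for n in range(1, 31)]
        assert (np.diff(fracs) >= -1e-15).all()
        np.testing.assert_allclose(fracs[-1], 1.0)


class TestTicAuc:
    def test_rectangle(self):
        trace = pd.DataFrame({"time_min": [0.0, 10.0], "intensity": [5.0, 5.0]})
        assert qc.tic_auc(trace) == 50.0

    def test_linear_ramp_closed_form(self):
        t = np.linspace(0, 4, 5)
        trace = pd.DataFrame({"time_min": t, "intensity": t})
        np.testing.assert_allclose(qc.tic_auc(trace), 8.0)

    def test_exact_on_piecewise_linear(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])
        y = np.array([0.0, 2.0, 2.0, 0.0])
        # trapezoid is exact for piecewise-linear traces: 1 + 4 + 3
        np.testing.assert_allclose(qc.tic_auc(pd.DataFrame({"time_min": t, "intensity": y})), 8.0)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            qc.tic_auc(pd.DataFrame({"time_min": [1.0], "intensity": [2.0]}))


class TestDepthOutliers:
    def test_gross_outlier_flagged(self):
        counts = pd.Series([7000] * 10 + [2000], index=[f"S{i}" for i in range(11)])
        flags = qc.depth_outliers(counts)
        assert flags.sum() == 1 and flags["S10"]

    def test_identical_counts_no_flags(self):
        assert not qc.depth_outliers(pd.Series([5000] * 8)).any()

    def test_matches_fence_oracle(self, cohort68):
        counts = qc.id_counts(cohort68.quant)
        flags = qc.depth_outliers(counts)
        q1, q3 = np.percentile(counts, [25, 75])
        fence = q1 - 1.5 * (q3 - q1)
        assert (flags == (counts < fence)).all()


class TestComplexConcordance:
    def test_zero_after_centering(self):
        mat = pd.DataFrame(
            {"S1": [1.0, 4.0], "S2": [2.0, 5.0], "S3": [3.0, 6.0]}, index=["MCM2", "MCM3"]
        )
        sd = qc.complex_concordance(mat, SignatureDefinition("MCM", ("MCM2", "MCM3")))
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_two_point_sd(self):
        # after centering, members disagree by 2 log2 units in S2
        mat = pd.DataFrame(
            {"S1": [0.0, 0.0], "S2": [1.0, -1.0], "S3": [-1.0, 1.0]},
            index=["MCM2", "MCM3"],
        )
        sd = qc.complex_concordance(mat, SignatureDefinition("MCM", ("MCM2", "MCM3")))
        np.testing.assert_allclose(sd["S2"], np.sqrt(2.0))

    def test_invariant_to_sample_shifts(self, small_cohort, sigs):
        mat = np.log2(small_cohort.quant)
        shifted = mat + np.arange(mat.shape[1])  # per-sample additive shift
        a = qc.complex_concordance(mat, sigs["MCM_COMPLEX"])
        b = qc.complex_concordance(shifted, sigs["MCM_COMPLEX"])
        pd.testing.assert_series_equal(a, b, atol=1e-9)

    def test_needs_two_members(self):
        mat = pd.DataFrame({"S1": [1.0]}, index=["MCM2"])
        with pytest.raises(DefinitionError):
            qc.complex_concordance(mat, SignatureDefinition("MCM", ("MCM2", "MCM3")))

    def test_sd_rises_with_contamination(self, cohort200, sigs):
        sd = qc.complex_concordance(np.log2(cohort200.quant), sigs["MCM_COMPLEX"])
        cf = cohort200.truth.samples["contaminant_signal_fraction"]
        quart = pd.qcut(cf, 4, labels=False)
        assert sd[quart == 3].mean() > sd[quart == 0].mean()


class TestDepthCorrelation:
    def test_perfectly_anti_monotone(self):
        m = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0])
        c = pd.Series([10, 20, 30, 40, 50])
        rho, p, method = qc.metric_depth_correlation(m, c)
        assert np.isclose(rho, -1.0) and method == "spearman"

    def test_independent_pairs_near_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rho, _, _ = qc.metric_depth_correlation(
                pd.Series(rng.normal(size=100)), pd.Series(rng.normal(size=100))
            )
            hits += abs(rho) < 0.3
        assert hits >= 19

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedMetricError):
            qc.metric_depth_correlation(pd.Series([1.0] * 6), pd.Series(range(6)))


def test_qc_report_assembles(small_cohort, sigs):
    report = qc.qc_report(
        small_cohort.precursors,
        small_cohort.quant,
        small_cohort.tic,
        sigs["SKIN_KERATINS"],
        complexes=[sigs["MCM_COMPLEX"]],
    )
    assert set(report.columns) >= {
        "id_count", "keratin_fraction", "top20_fraction", "tic_auc", "depth_outlier",
        "MCM_COMPLEX_sd",
    }
    assert report["keratin_fraction"].between(0, 1).all()
    assert report["top20_fraction"].between(0, 1).all()
    assert (report["id_count"] <= len(small_cohort.quant)).all()
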