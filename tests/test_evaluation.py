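"""Split design, Eq-style metrics, and paired model comparison."""

import numpy as np
import pytest
from scipy import stats

from ltindex.evaluation import (
    SplitScheme,
    aggregate_report,
    compare_families,
    cv_percent,
    evaluate_model,
    make_splits,
    mre,
    paired_t,
    r2,
    rmse,
)
from ltindex.indices import BandPair
from ltindex.regression_models import fit_index_model
from conftest import make_spectrum_set

import pandas as pd


class TestMakeSplits:
    def test_study_sized_partition_counts(self):
        scheme = make_splits(152, SplitScheme(base_seed=0))
        assert len(scheme.splits) == 10
        for cal, val in scheme.splits:
            assert len(cal) == 114 and len(val) == 38

    def test_deterministic_and_disjoint(self):
        a = make_splits(40, SplitScheme(n_repeats=4, base_seed=9))
        b = make_splits(40, SplitScheme(n_repeats=4, base_seed=9))
        for (c1, v1), (c2, v2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(c1, c2)
            np.testing.assert_array_equal(v1, v2)
            assert set(c1) | set(v1) == set(range(40))
            assert not set(c1) & set(v1)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitScheme(calibration_fraction=1.0)


class TestMetrics:
    def test_perfect_fit(self):
        assert rmse([4.0, 6.0], [4.0, 6.0]) == 0.0
        assert mre([4.0, 6.0], [4.0, 6.0]) == 0.0
        assert r2([4.0, 6.0], [4.0, 6.0]) == pytest.approx(1.0)

    def test_hand_computed_rmse_and_mre(self):
        y, yhat = [4.0, 5.0], [5.0, 4.5]
        assert rmse(y, yhat) == pytest.approx(np.sqrt(0.625), abs=1e-12)
        assert mre(y, yhat) == pytest.approx(17.5, abs=1e-12)

    def test_validation_r2_can_be_negative(self):
        assert r2([0.0001, 1.0], [2.0, 2.0]) < 0.0

    def test_constant_observed_flags(self):
        assert r2([4.0, 4.0], [4.0, 4.0]) == 1.0        # SSres = SStot = 0
        assert np.isnan(r2([4.0, 4.0], [4.0, 5.0]))     # SStot = 0, SSres > 0

    def test_cv_hand_computed(self):
        assert cv_percent([4.0, 4.2, 4.4]) == pytest.approx(0.2 / 4.2 * 100,
                                                            abs=1e-10)

    def test_cv_scale_invariance_and_constant(self):
        x = np.array([3.0, 5.0, 8.0])
        assert cv_percent(x) == pytest.approx(cv_percent(7.3 * x), abs=1e-9)
        assert cv_percent([4.0, 4.0, 4.0]) == 0.0

    def test_metrics_sample_order_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(3, 8, 25)
        yhat = y + rng.normal(0, 0.4, 25)
        perm = rng.permutation(25)
        assert r2(y, yhat) == pytest.approx(r2(y[perm], yhat[perm]))
        assert rmse(y, yhat) == pytest.approx(rmse(y[perm], yhat[perm]))
        assert mre(y, yhat) == pytest.approx(mre(y[perm], yhat[perm]))


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1,2,3): mean 2, sd 1 → t = 2√3, df 2
        t, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-12)
        assert p == pytest.approx(2.0 * stats.t.sf(2.0 * np.sqrt(3.0), df=2),
                                  abs=1e-12)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_antisymmetry(self):
        a, b = [0.8, 0.7, 0.9, 0.75], [0.6, 0.72, 0.8, 0.7]
        t_ab, p_ab = paired_t(a, b)
        t_ba, p_ba = paired_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_identical_vectors_degenerate(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(t) and np.isnan(p)


class TestEvaluateAndAggregate:
    def planted_model(self):
        rng = np.random.default_rng(5)
        R = rng.uniform(0.2, 0.8, (40, 3))
        ssc = 2.0 * (R[:, 0] - R[:, 2]) + 5.0
        ss = make_spectrum_set(R, ssc)
        model = fit_index_model(ss, "DSI", bands=BandPair(ss.wavelengths[0],
                                                          ss.wavelengths[2]))
        return model, ss

    def test_perfect_model_metrics(self):
        model, ss = self.planted_model()
        row = evaluate_model(model, ss.subset(range(30)), ss.subset(range(30, 40)))
        assert row["Rc2"] == pytest.approx(1.0, abs=1e-10)
        assert row["Rp2"] == pytest.approx(1.0, abs=1e-10)
        assert row["RMSEC"] == pytest.approx(0.0, abs=1e-6)
        assert row["RMSEP"] == pytest.approx(0.0, abs=1e-6)
        assert row["MRE"] == pytest.approx(0.0, abs=1e-5)

    def test_aggregate_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        rows = []
        for d in range(1, 6):
            for fam in ("ltDSI", "PLS"):
                rows.append({"dataset": d, "family": fam,
                             "Rc2": rng.uniform(0.6, 0.9),
                             "Rp2": rng.uniform(0.5, 0.85),
                             "RMSEC": rng.uniform(0.5, 0.9),
                             "RMSEP": rng.uniform(0.6, 1.0),
                             "MRE": rng.uniform(9, 15)})
        report = pd.DataFrame(rows)
        agg = aggregate_report(report)
        sub = report[report["family"] == "PLS"]
        got = agg[(agg["family"] == "PLS") & (agg["stat"] == "mean")]["Rp2"].iloc[0]
        assert got == pytest.approx(sub["Rp2"].mean())
        got_min = agg[(agg["family"] == "ltDSI") & (agg["stat"] == "min")]["RMSEP"].iloc[0]
        assert got_min == pytest.approx(report[report["family"] == "ltDSI"]["RMSEP"].min())

    def test_compare_families_matches_paired_t(self):
        rng = np.random.default_rng(7)
        rows = []
        for d in range(1, 11):
            rows.append({"dataset": d, "family": "ltDSI",
                         "Rp2": rng.uniform(0.7, 0.9), "RMSEP": rng.uniform(0.5, 0.7),
                         "MRE": rng.uniform(9, 11)})
            rows.append({"dataset": d, "family": "PLS",
                         "Rp2": rng.uniform(0.5, 0.8), "RMSEP": rng.uniform(0.7, 1.0),
                         "MRE": rng.uniform(10, 15)})
        report = pd.DataFrame(rows)
        table = compare_families(report, "ltDSI", "PLS")
        a = report[report["family"] == "ltDSI"].sort_values("dataset")
        b = report[report["family"] == "PLS"].sort_values("dataset")
        for _, row in table.iterrows():
            t, p = paired_t(a[row["metric"]].to_numpy(), b[row["metric"]].to_numpy())
            assert row["t"] == pytest.approx(t) and row["p"] == pytest.approx(p)
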