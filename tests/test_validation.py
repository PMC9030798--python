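import numpy as np
import pytest

from fieldqsar.pls_qsar import CvResult
from fieldqsar.validation import (MetricReport, error_stats, external_q2,
                                  golbraikh_tropsha, metric_battery,
                                  report_table, rm2_metrics, stratified_split,
                                  threshold_report)


class TestStratifiedSplit:
    def test_twelve_compounds_give_3_test_9_train(self):
        y = np.linspace(5.0, 9.0, 12)
        scheme = stratified_split(y, seed=0)
        for train, test in scheme.sets():
            assert len(test) == 3 and len(train) == 9

    def test_test_sets_partition_the_dataset(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(5, 9, size=37)
        scheme = stratified_split(y, seed=3)
        tests = [set(t) for _, t in scheme.sets()]
        all_ids = set().union(*tests)
        assert all_ids == {str(i) for i in range(37)}
        for i, a in enumerate(tests):
            for b in tests[i + 1:]:
                assert not (a & b)

    def test_fold_sizes_within_stratum_differ_by_at_most_one(self):
        y = np.random.default_rng(1).uniform(5, 9, 50)
        scheme = stratified_split(y, seed=1)
        for s in range(3):
            sizes = [sum(1 for st, f in scheme.assignments.values()
                         if st == s and f == k) for k in range(4)]
            assert max(sizes) - min(sizes) <= 1

    def test_strata_are_activity_ordered(self):
        y = np.random.default_rng(2).uniform(5, 9, 30)
        scheme = stratified_split(y, seed=2)
        by_stratum = {s: [y[int(i)] for i, (st, _) in scheme.assignments.items()
                          if st == s] for s in range(3)}
        assert max(by_stratum[0]) <= min(by_stratum[2])

    def test_deterministic_under_seed(self):
        y = np.random.default_rng(3).uniform(5, 9, 24)
        assert stratified_split(y, seed=7).assignments == \
            stratified_split(y, seed=7).assignments

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.linspace(5, 9, 11), seed=0)


class TestGolbraikhTropsha:
    def test_identity_predictions(self, toy_xy):
        y, _ = toy_xy
        gt = golbraikh_tropsha(y, y)
        assert gt["k"] == pytest.approx(1.0)
        assert gt["k_prime"] == pytest.approx(1.0)
        assert gt["r0_2"] == pytest.approx(1.0)
        assert gt["r0p_2"] == pytest.approx(1.0)
        assert gt["abs_r0_diff"] == pytest.approx(0.0, abs=1e-12)
        assert gt["rel_r0_gap"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_vectors_match_formula_oracle(self, toy_xy):
        y, yh = toy_xy
        gt = golbraikh_tropsha(y, yh)
        # independent, written-out evaluation of every definition
        k = float(sum(a * b for a, b in zip(y, yh)) / sum(b * b for b in yh))
        kp = float(sum(a * b for a, b in zip(y, yh)) / sum(a * a for a in y))
        ybar, yhbar = y.mean(), yh.mean()
        r0 = 1 - sum((a - k * b) ** 2 for a, b in zip(y, yh)) / \
            sum((a - ybar) ** 2 for a in y)
        r0p = 1 - sum((b - kp * a) ** 2 for a, b in zip(y, yh)) / \
            sum((b - yhbar) ** 2 for b in yh)
        assert gt["k"] == pytest.approx(k, abs=1e-12)
        assert gt["k_prime"] == pytest.approx(kp, abs=1e-12)
        assert gt["r0_2"] == pytest.approx(r0, abs=1e-12)
        assert gt["r0p_2"] == pytest.approx(r0p, abs=1e-12)
        assert gt["abs_r0_diff"] == pytest.approx(abs(r0 - r0p), abs=1e-12)

    def test_reorder_invariance(self, toy_xy):
        y, yh = toy_xy
        perm = np.array([3, 1, 5, 0, 2, 4])
        a = golbraikh_tropsha(y, yh)
        b = golbraikh_tropsha(y[perm], yh[perm])
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            golbraikh_tropsha([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRm2:
    def test_perfect_model(self):
        assert rm2_metrics(1.0, 1.0, 1.0)["rm2"] == pytest.approx(1.0)

    def test_published_worked_example(self):
        # printed test-set statistics of a CoMFA external validation
        out = rm2_metrics(0.684, 0.640, 0.664)
        assert out["rm2"] == pytest.approx(0.540, abs=0.002)
        assert out["rm2_prime"] == pytest.approx(0.587, abs=0.002)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rm2_metrics(0.5, -0.1, 0.4)

    def test_r0_above_r2_clamped(self):
        out = rm2_metrics(0.6, 0.7, 0.5)
        assert out["rm2"] == pytest.approx(0.6)


class TestExternalQ2:
    def test_perfect_predictions_give_unity(self, toy_xy):
        y, _ = toy_xy
        q = external_q2(y, y, y + 0.1)
        for key in ("qf1_2", "qf2_2", "qf3_2", "q_ccc2", "r_pred2"):
            assert q[key] == pytest.approx(1.0)

    def test_train_mean_predictor_zeroes_qf1(self, toy_xy):
        y, _ = toy_xy
        y_train = y + 0.3
        yh = np.full_like(y, y_train.mean())
        assert external_q2(y, yh, y_train)["qf1_2"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_vectors_match_formula_oracle(self, toy_xy):
        y, yh = toy_xy
        y_train = np.array([5.0, 6.1, 7.2, 8.3, 6.5, 7.9, 8.8])
        q = external_q2(y, yh, y_train)
        press = sum((a - b) ** 2 for a, b in zip(y, yh))
        qf1 = 1 - press / sum((a - y_train.mean()) ** 2 for a in y)
        qf2 = 1 - press / sum((a - y.mean()) ** 2 for a in y)
        qf3 = 1 - (press / len(y)) / \
            (sum((t - y_train.mean()) ** 2 for t in y_train) / len(y_train))
        sxy = np.mean((y - y.mean()) * (yh - yh.mean()))
        ccc = 2 * sxy / (y.var() + yh.var() + (y.mean() - yh.mean()) ** 2)
        assert q["qf1_2"] == pytest.approx(qf1, abs=1e-12)
        assert q["qf2_2"] == pytest.approx(qf2, abs=1e-12)
        assert q["qf3_2"] == pytest.approx(qf3, abs=1e-12)
        assert q["q_ccc2"] == pytest.approx(ccc, abs=1e-12)
        assert q["r_pred2"] == q["qf1_2"]

    def test_qf1_equals_qf2_when_means_agree(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        yh = y + np.array([0.2, -0.2, 0.1, -0.1])
        y_train = np.array([4.5, 6.5, 7.5, 7.5])  # same mean as y
        q = external_q2(y, yh, y_train)
        assert q["qf1_2"] == pytest.approx(q["qf2_2"], abs=1e-12)

    def test_ccc_strictly_decreases_under_bias(self, toy_xy):
        y, _ = toy_xy
        base = external_q2(y, y, y + 0.1)["q_ccc2"]
        biased = external_q2(y, y + 0.5, y + 0.1)["q_ccc2"]
        assert biased < base

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            external_q2([5.0, 5.0], [5.1, 5.2], [6.0, 7.0])


class TestErrorStats:
    def test_identity_gives_zeros(self, toy_xy):
        y, _ = toy_xy
        s = error_stats(y, y)
        assert s["rss"] == s["rmse"] == s["chi2"] == s["mae"] == 0.0

    def test_unbiased_residuals_small_mae_large_rmse(self):
        y = np.array([6.0, 7.0, 6.0, 7.0])
        yh = y + np.array([0.3, -0.3, 0.3, -0.3])
        s = error_stats(y, yh)
        assert s["mae"] < 1e-12
        assert s["rmse"] == pytest.approx(0.3)
        assert s["mean_abs_error"] == pytest.approx(0.3)

    def test_toy_vectors_match_formula_oracle(self, toy_xy):
        y, yh = toy_xy
        s = error_stats(y, yh)
        e = y - yh
        assert s["rss"] == pytest.approx(sum(v * v for v in e), abs=1e-12)
        assert s["rmse"] == pytest.approx(np.sqrt(np.mean(e ** 2)), abs=1e-12)
        assert s["chi2"] == pytest.approx(sum(v * v / abs(p) for v, p in zip(e, yh)),
                                          abs=1e-12)


class TestThresholds:
    def _good_cv(self):
        return CvResult(q2=0.655, onc=6, sep=0.456, r2=0.854, see=0.296,
                        f_value=148.4, per_component_q2=np.array([0.655]))

    def test_strong_internal_model_passes(self, toy_xy):
        y, yh = toy_xy
        rep = metric_battery(y + 0.2, yh + 0.2, y, yh)
        flags = threshold_report(rep, self._good_cv())
        assert flags["q2>0.5"] and flags["r2>0.6"] and flags["F>100"]

    def test_weak_q2_fails(self, toy_xy):
        y, yh = toy_xy
        rep = metric_battery(y + 0.2, yh + 0.2, y, yh)
        cv = self._good_cv()
        cv.q2 = 0.3
        assert not threshold_report(rep, cv)["q2>0.5"]

    def test_slope_boundary_inclusive(self):
        rep = MetricReport(k=0.85, k_prime=1.15)
        flags = threshold_report(rep)
        assert flags["0.85<=k<=1.15"]
        assert flags["0.85<=k_prime<=1.15"]

    def test_chi2_bound_depends_on_context(self):
        rep = MetricReport(chi2=0.7)
        assert threshold_report(rep, context="set")["chi2<1.0"]
        assert not threshold_report(rep, context="all")["chi2<0.5"]

    def test_report_table_layout(self, toy_xy):
        y, yh = toy_xy
        rep = metric_battery(y + 0.2, yh + 0.2, y, yh)
        df = report_table({"SET-A": rep}, {"SET-A": self._good_cv()})
        assert "SET-A" in df.columns
        assert df.columns[-1] == "threshold"
        assert "rm2" in df.index and "q_ccc2" in df.index
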