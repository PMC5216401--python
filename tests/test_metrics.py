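"""Validation-statistics tests against independent direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from docksel.metrics import (ClassificationReport, ConfusionMatrix,
                             classification_report, criteria_battery,
                             headline_threshold_checks,
                             pose_selection_confusion, q2_cross_validation,
                             regression_report)

from oracles import oracle_regression_stats


FIELDS = ["r2", "q2", "q2_f1", "mae", "rmse", "s", "delta_max", "k",
          "k_prime", "r0_2", "r0_prime_2", "rm2", "rm2_prime", "rm2_avg",
          "rm2_delta", "ccc"]


class TestRegressionReport:
    def test_matches_direct_formula_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.normal(5, 2, 10)
            p = y + rng.normal(0, rng.uniform(0.1, 2.0), 10)
            rep = regression_report(y, p).to_dict()
            exp = oracle_regression_stats(list(y), list(p))
            for f in FIELDS:
                assert rep[f] == pytest.approx(exp[f], abs=1e-10), f

    def test_perfect_agreement(self):
        rep = regression_report([1, 2, 3], [1, 2, 3])
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.k == pytest.approx(1.0)
        assert rep.r0_2 == pytest.approx(1.0)
        assert rep.rm2 == pytest.approx(1.0)
        assert rep.ccc == pytest.approx(1.0)

    def test_doubled_predictions_hand_values(self):
        # y=(1,2,3), p=(2,4,6): perfect correlation, slope k = 1/2,
        # CCC = 2*cov / (var_y + var_p + shift^2) = (8/3)/(22/3) = 8/22
        rep = regression_report([1, 2, 3], [2, 4, 6])
        assert rep.r2 == pytest.approx(1.0)
        assert rep.k == pytest.approx(0.5)
        assert rep.r0_2 == pytest.approx(1.0)
        assert rep.ccc == pytest.approx(8 / 22, abs=1e-12)

    def test_unit_shift_ccc(self):
        rep = regression_report([0, 1, 2], [1, 2, 3])
        assert rep.ccc == pytest.approx(4 / 7, abs=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_report([2, 2, 2], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            regression_report([1, 2, 3], [1, 2])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_ccc_bounded_by_pearson_r(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, 12)
        p = rng.normal(0, 2, 12)
        if np.ptp(y) == 0 or np.ptp(p) == 0:
            return
        rep = regression_report(y, p)
        r = np.corrcoef(y, p)[0, 1]
        assert abs(rep.ccc) <= abs(r) + 1e-12
        assert -1 - 1e-12 <= rep.ccc <= 1 + 1e-12
        assert rep.rm2 <= rep.r2 + 1e-12


class TestQ2CrossValidation:
    def test_noiseless_interpolable_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = 3 * X[:, 0] - 2 * X[:, 1]
        from sklearn.linear_model import LinearRegression
        q2 = q2_cross_validation(X, y, lambda a, b: LinearRegression().fit(a, b),
                                 folds=10, seed=1)
        assert q2 >= 0.99

    def test_mean_only_trainer_not_predictive(self):
        # predicting the training mean gives PRESS >= SS, hence q2cv <= 0
        class MeanModel:
            def __init__(self, mu):
                self.mu = mu

            def predict(self, X):
                return np.full(len(X), self.mu)

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        q2 = q2_cross_validation(X, y, lambda a, b: MeanModel(b.mean()),
                                 folds=10, seed=2)
        assert q2 <= 0.0

    def test_folds_equal_n_is_leave_one_out(self):
        from sklearn.linear_model import LinearRegression
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        y = X[:, 0] + 0.5 * rng.normal(size=12)
        q2 = q2_cross_validation(X, y, lambda a, b: LinearRegression().fit(a, b),
                                 folds=12, seed=0)
        # explicit LOO enumeration
        preds = np.empty(12)
        for i in range(12):
            mask = np.ones(12, bool)
            mask[i] = False
            m = LinearRegression().fit(X[mask], y[mask])
            preds[i] = m.predict(X[i:i + 1])[0]
        expected = 1 - ((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert q2 == pytest.approx(expected, abs=1e-12)


class TestCriteriaBattery:
    def test_perfect_predictions_pass_everything(self):
        y = [3.1, 4.5, 5.0, 6.2, 7.7, 8.4]
        rep = regression_report(y, y)
        report = criteria_battery(rep, rep, q2cv=1.0)
        assert report.overall

    def test_constant_mean_predictions_fail_q2(self):
        y = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        p = np.full(5, y.mean()) + np.array([1e-9, -1e-9, 1e-9, -1e-9, 1e-9])
        rep_te = regression_report(y, p)
        rep_tr = regression_report(y, y)
        report = criteria_battery(rep_tr, rep_te)
        assert rep_te.q2_f1 <= 0 + 1e-6
        assert not report["q2_external"].passed
        assert not report.overall

    def test_headline_thresholds_on_reported_statistics(self):
        # a model reporting train r2 0.967, external q2 0.894 and
        # q2cv 0.899 clears every headline threshold
        checks = headline_threshold_checks(0.967, 0.894, 0.899)
        assert all(checks.values())


class TestClassification:
    def test_hand_computed_matrix(self):
        rep = classification_report(ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.mcc == pytest.approx(10 / np.sqrt(600), abs=1e-12)
        assert rep.g_mean == pytest.approx(np.sqrt(0.48), abs=1e-12)

    def test_perfect_matrix(self):
        rep = classification_report(ConfusionMatrix(tp=5, fp=0, fn=0, tn=10))
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (1, 1, 1)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.g_mean == pytest.approx(1.0)

    def test_total_failure(self):
        rep = classification_report(ConfusionMatrix(tp=0, fp=3, fn=2, tn=0))
        assert rep.sensitivity == 0 and rep.specificity == 0
        assert rep.g_mean == 0
        assert rep.mcc <= 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_rates_bounded_and_gmean_identity(self, tp, fp, fn, tn):
        rep = classification_report(ConfusionMatrix(tp, fp, fn, tn))
        for v in (rep.sensitivity, rep.specificity, rep.accuracy):
            assert 0 <= v <= 1
        assert rep.g_mean**2 == pytest.approx(
            rep.sensitivity * rep.specificity, abs=1e-12)
        assert -1 - 1e-12 <= rep.mcc <= 1 + 1e-12


class TestPoseSelectionConfusion:
    def _table(self):
        rows = []
        for g, rmsds in (("A", [0.2, 1.0, 2.0]), ("B", [0.5, 0.3, 4.0])):
            for i, r in enumerate(rmsds, start=1):
                rows.append((g, "S1", 1, 1, i, 0.0, r))
        return pd.DataFrame(rows, columns=[
            "ligand_id", "structure_id", "conformer_id", "run_id", "pose_id",
            "term_1", "observed_rmsd"])

    def test_one_right_one_wrong_selection(self):
        table = self._table()
        # pick pose 1 for both groups: right for A (0.2), wrong for B (0.3 is pose 2)
        sel = table[table.pose_id == 1]
        cm = pose_selection_confusion(sel, table, ["ligand_id"])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 3)
        rep = classification_report(cm)
        assert rep.sensitivity == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(0.75)

    def test_all_correct(self):
        table = self._table()
        sel = table.loc[[0, 4]]  # pose 1 of A, pose 2 of B: both minima
        cm = pose_selection_confusion(sel, table, ["ligand_id"])
        assert cm.fp == 0 and cm.fn == 0

    def test_tied_minimum_either_selection_is_tp(self):
        table = self._table()
        table.loc[1, "observed_rmsd"] = 0.2  # A poses 1 and 2 tie at minimum
        for pose in (1, 2):
            sel = pd.concat([table[(table.ligand_id == "A")
                                   & (table.pose_id == pose)],
                             table.loc[[4]]])
            cm = pose_selection_confusion(sel, table, ["ligand_id"])
            assert cm.fp == 0

    def test_missing_selection_rejected(self):
        table = self._table()
        sel = table.loc[[0]]  # no selection for group B
        with pytest.raises(ValueError, match="without a selection"):
            pose_selection_confusion(sel, table, ["ligand_id"])
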