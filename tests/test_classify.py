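"""Logistic diagnostic models, ROC/AUC, OR_IQR, deviance test and CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uroev
from uroev.classify import (ModelSpec, classification_metrics,
                            cross_validate, deviance_test, fit_logistic,
                            odds_ratio_iqr, roc_auc, youden_threshold)

from conftest import make_sheet


def predictors_for(sheet, values, name="g1"):
    return pd.DataFrame({name: values}, index=sheet.sample_ids)


class TestModelSpec:
    def test_limits(self):
        with pytest.raises(ValueError):
            ModelSpec(())
        with pytest.raises(ValueError):
            ModelSpec(("a", "b", "c", "d", "e"))
        with pytest.raises(ValueError):
            ModelSpec(("a", "a"))
        with pytest.raises(ValueError):
            ModelSpec(("a",), ("smoking",))


class TestFitLogistic:
    def test_intercept_only_probability_is_prevalence(self):
        sheet = make_sheet(47, 16)
        rng = np.random.default_rng(0)
        pred = predictors_for(sheet, rng.normal(0, 1, 63))
        fit = fit_logistic(ModelSpec(("g1",)), pred, sheet)
        from uroev.classify import intercept_only_fit
        null = intercept_only_fit(fit)
        np.testing.assert_allclose(null.fitted, 47 / 63, rtol=1e-8)

    def test_coefficient_recovery_large_n(self):
        rng = np.random.default_rng(1)
        n = 2000
        sheet = make_sheet(n // 2, n // 2, seed=1)
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-x))  # beta = (0, 1)
        groups = np.where(rng.random(n) < p, "case", "control")
        sheet = make_sheet(n // 2, n // 2, seed=1, group=groups)
        pred = predictors_for(sheet, x)
        fit = fit_logistic(ModelSpec(("g1",)), pred, sheet)
        assert 0.85 <= fit.params["g1"] <= 1.15

    def test_null_predictor_wald_calibration(self):
        """z for an uninformative predictor is ~N(0,1): ~95% within 1.96."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 200
        sheet = make_sheet(250, 250, seed=2)
        for _ in range(reps):
            pred = predictors_for(sheet, rng.normal(0, 1, 500))
            fit = fit_logistic(ModelSpec(("g1",)), pred, sheet)
            z = fit.params["g1"] / fit.bse["g1"]
            hits += abs(z) < 1.96
        assert 0.91 <= hits / reps <= 0.99

    def test_matches_newton_oracle(self):
        """Agrees with a hand-rolled Newton-Raphson MLE to 1e-6."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 30
            sheet = make_sheet(16, 14, seed=int(rng.integers(1e6)))
            X2 = rng.normal(0, 1, (n, 2))
            pred = pd.DataFrame(X2, index=sheet.sample_ids,
                                columns=["g1", "g2"])
            fit = fit_logistic(ModelSpec(("g1", "g2")), pred, sheet)
            if not fit.converged:
                continue
            # oracle: Newton iterations on the same design
            Xm = fit.X.to_numpy()
            y = fit.y.to_numpy()
            beta = np.zeros(Xm.shape[1])
            for _ in range(50):
                mu = 1 / (1 + np.exp(-Xm @ beta))
                W = mu * (1 - mu)
                grad = Xm.T @ (y - mu)
                H = Xm.T @ (Xm * W[:, None])
                step = np.linalg.solve(H, grad)
                beta = beta + step
                if np.abs(step).max() < 1e-12:
                    break
            np.testing.assert_allclose(fit.params.to_numpy(), beta,
                                       atol=1e-6)

    def test_separation_flagged_not_raised(self):
        sheet = make_sheet(10, 10, seed=4)
        x = np.r_[np.ones(10), -np.ones(10)]  # perfectly separates
        fit = fit_logistic(ModelSpec(("g1",)), predictors_for(sheet, x),
                           sheet)
        assert not fit.converged


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_hand_counted_pairs(self):
        # pairs won: 3 of 4 -> 0.75
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_anchored(self):
        points, _ = roc_auc([0.3, 0.7, 0.6], [0, 1, 1])
        assert (points.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (points.iloc[-1][["fpr", "tpr"]] == 1).all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        _, a1 = roc_auc(s, y)
        _, a2 = roc_auc(np.exp(3 * s) + 7, y)
        assert a1 == pytest.approx(a2)

    def test_matches_pair_counting_oracle(self):
        """AUC equals explicit pair counting with half-credit ties."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            s = np.round(rng.normal(0, 1, n), 1)  # rounding makes ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            _, auc = roc_auc(s, y)
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))


class TestMetrics:
    def test_all_correct(self):
        assert classification_metrics([0.9, 0.1], [1, 0]) == (1.0, 1.0, 1.0)

    def test_predict_everything_case(self):
        y = [1] * 47 + [0] * 16
        p = [0.9] * 63
        sens, spec, acc = classification_metrics(p, y)
        assert (sens, spec) == (1.0, 0.0)
        assert acc == pytest.approx(47 / 63)

    def test_constructed_confusion_table(self):
        # TP=36, FN=18, TN=21, FP=3
        y = [1] * 54 + [0] * 24
        p = [0.9] * 36 + [0.1] * 18 + [0.1] * 21 + [0.9] * 3
        sens, spec, acc = classification_metrics(p, y)
        assert sens == pytest.approx(36 / 54)
        assert spec == pytest.approx(21 / 24)
        assert acc == pytest.approx(57 / 78)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(47), np.zeros(16)]
        p = rng.random(63)
        sens, spec, acc = classification_metrics(p, y)
        assert acc == pytest.approx((sens * 47 + spec * 16) / 63)


class TestOddsRatio:
    def _fit(self, beta_sign=1.0, seed=8):
        rng = np.random.default_rng(seed)
        n = 200
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-beta_sign * 1.5 * x))
        groups = np.where(rng.random(n) < p, "case", "control")
        sheet = make_sheet(100, 100, seed=seed, group=groups)
        pred = predictors_for(sheet, x)
        return fit_logistic(ModelSpec(("g1",)), pred, sheet)

    def test_direction_convention(self):
        """Lower expression in cases (beta < 0) gives OR_IQR < 1."""
        fit = self._fit(beta_sign=-1.0)
        out = odds_ratio_iqr(fit)
        assert out.loc["g1", "or_iqr"] < 1

    def test_closed_form(self):
        fit = self._fit()
        out = odds_ratio_iqr(fit)
        x = fit.X["g1"].to_numpy()
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        assert out.loc["g1", "or_iqr"] == pytest.approx(
            np.exp(fit.params["g1"] * iqr))
        assert out.loc["g1", "iqr"] == pytest.approx(iqr)

    def test_log_base_invariance(self):
        """OR_IQR is unchanged if predictors switch log base."""
        fit_e = self._fit()
        sheet = make_sheet(100, 100, seed=8,
                           group=np.where(fit_e.y.to_numpy() == 1, "case",
                                          "control"))
        pred2 = pd.DataFrame({"g1": fit_e.X["g1"].to_numpy() / np.log(2)},
                             index=fit_e.X.index)
        fit_2 = fit_logistic(ModelSpec(("g1",)), pred2, sheet)
        o_e = odds_ratio_iqr(fit_e).loc["g1", "or_iqr"]
        o_2 = odds_ratio_iqr(fit_2).loc["g1", "or_iqr"]
        assert o_e == pytest.approx(o_2, rel=1e-6)


class TestDevianceTest:
    def test_null_equals_fit(self):
        sheet = make_sheet(20, 20, seed=9)
        rng = np.random.default_rng(9)
        pred = predictors_for(sheet, rng.normal(0, 1, 40))
        fit = fit_logistic(ModelSpec(("g1",)), pred, sheet)
        assert deviance_test(fit, fit) == pytest.approx(1.0)

    def test_chi_squared_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=0.001)


class TestCrossValidation:
    def test_fold_sizes_at_study_shape(self):
        """54/24 into 5 folds: cases {11x4,10}, controls {5x4,4}."""
        sheet = make_sheet(54, 24, seed=10)
        rng = np.random.default_rng(10)
        x = np.where(sheet.rows["group"] == "case", -1.0, 1.0) \
            + rng.normal(0, 1.2, 78)
        cv = cross_validate(ModelSpec(("g1",)), predictors_for(sheet, x),
                            sheet, n_repeats=3,
                            min_per_fold={"case": 10, "control": 4}, seed=1)
        comp = cv.fold_composition
        for rep, grp in comp.groupby("repeat"):
            assert sorted(grp["n_case"]) == [10, 11, 11, 11, 11]
            assert sorted(grp["n_control"]) == [4, 5, 5, 5, 5]

    def test_shortfall_error_lists_class(self):
        sheet = make_sheet(12, 6, seed=11)
        pred = predictors_for(sheet, np.zeros(18))
        with pytest.raises(ValueError, match="case"):
            cross_validate(ModelSpec(("g1",)), pred, sheet,
                           min_per_fold={"case": 10, "control": 1},
                           n_repeats=1)

    def test_same_seed_identical_report(self):
        sheet = make_sheet(30, 15, seed=12)
        rng = np.random.default_rng(12)
        x = np.where(sheet.rows["group"] == "case", -0.8, 0.8) \
            + rng.normal(0, 1, 45)
        pred = predictors_for(sheet, x)
        cv1 = cross_validate(ModelSpec(("g1",)), pred, sheet, n_repeats=5,
                             seed=7)
        cv2 = cross_validate(ModelSpec(("g1",)), pred, sheet, n_repeats=5,
                             seed=7)
        pd.testing.assert_frame_equal(cv1.per_eval, cv2.per_eval)

    def test_every_test_fold_contains_both_classes(self):
        sheet = make_sheet(30, 15, seed=13)
        pred = predictors_for(sheet,
                              np.random.default_rng(13).normal(0, 1, 45))
        cv = cross_validate(ModelSpec(("g1",)), pred, sheet, n_repeats=4,
                            seed=3)
        comp = cv.fold_composition
        assert (comp["n_case"] > 0).all() and (comp["n_control"] > 0).all()


class TestYouden:
    def test_youden_maximizes_j(self):
        rng = np.random.default_rng(14)
        p = rng.random(60)
        y = (rng.random(60) < p).astype(int)
        thr = youden_threshold(p, y)
        sens, spec, _ = classification_metrics(p, y, threshold=thr)
        j_best = sens + spec - 1
        for t in np.linspace(0.01, 0.99, 99):
            s, sp, _ = classification_metrics(p, y, threshold=t)
            assert s + sp - 1 <= j_best + 1e-9
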