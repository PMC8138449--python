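import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import ppgaf as pg

from .oracles import auc_pair_oracle, logistic_nll


def _toy_data(seed=0, n=200, beta=(0.8, -0.5), intercept=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    y = (rng.uniform(size=n) < expit(intercept + X @ np.asarray(beta))).astype(int)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(len(beta))]), y


class TestFitLogistic:
    def test_symmetric_data_zero_intercept(self):
        x = np.concatenate([np.linspace(0.5, 3, 40), -np.linspace(0.5, 3, 40)])
        y = np.concatenate([np.ones(40), np.zeros(40)])
        m = pg.fit_logistic(x[:, None], y)
        assert abs(m.intercept) < 1e-6

    def test_likelihood_matches_independent_optimizer(self):
        X, y = _toy_data(seed=1)
        m = pg.fit_logistic(X, y)
        beta = np.concatenate([[m.intercept], m.coefficients])
        res = minimize(logistic_nll, np.zeros(3), args=(X.to_numpy(), y),
                       method="BFGS")
        assert logistic_nll(beta, X.to_numpy(), y) == pytest.approx(res.fun, abs=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _toy_data(seed=2)
        m = pg.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(
            np.concatenate([[m.intercept], m.coefficients]), ref.params, atol=1e-6)
        np.testing.assert_allclose(m.stderr, ref.bse, atol=1e-5)

    def test_odds_ratio_is_exp_estimate(self):
        X, y = _toy_data(seed=3)
        m = pg.fit_logistic(X, y)
        summ = m.summary()
        np.testing.assert_allclose(summ["OR"], np.exp(summ["Estimate"]), rtol=1e-12)
        assert (summ.loc[summ["Estimate"] < 0, "OR"] < 1).all()

    def test_perfect_separation_flagged_not_fatal(self):
        x = np.concatenate([np.ones(20), -np.ones(20)])[:, None]
        y = np.concatenate([np.ones(20), np.zeros(20)])
        with pytest.warns(UserWarning, match="converge"):
            m = pg.fit_logistic(x, y)
        assert not m.converged
        assert np.isfinite(m.coefficients).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pg.fit_logistic(np.ones((5, 1)), np.ones(5))


class TestPredict:
    def test_zero_logit_classified_af_at_default_cutoff(self):
        m = pg.PredictorModel(0.0, np.zeros(2), ["a", "b"])
        p, call = pg.predict(m, pd.DataFrame({"a": [0.0], "b": [0.0]}))
        assert p[0] == 0.5 and call[0] == 1

    def test_negative_intercept_probability(self):
        m = pg.PredictorModel(-3.723, np.zeros(1), ["x"])
        p, call = pg.predict(m, pd.DataFrame({"x": [0.0]}))
        assert p[0] == pytest.approx(0.0236, abs=5e-4)
        assert call[0] == 0

    def test_missing_feature_rejected(self):
        m = pg.PredictorModel(0.0, np.ones(1), ["x"])
        with pytest.raises(ValueError):
            pg.predict(m, pd.DataFrame({"y": [1.0]}))


class TestBackwardSelect:
    def test_alpha_one_keeps_full_model(self):
        X, y = _toy_data(seed=4)
        m = pg.backward_select(X, y, alpha=1.0)
        assert set(m.feature_names) == set(X.columns)
        assert m.selection_trace == []

    def test_tiny_alpha_empties_model(self):
        X, y = _toy_data(seed=5)
        with pytest.warns(UserWarning, match="every feature"):
            m = pg.backward_select(X, y, alpha=1e-12)
        assert m.feature_names == []
        assert len(m.selection_trace) == X.shape[1]

    def test_single_informative_feature_retained(self):
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                rng = np.random.default_rng(2000 + seed)
                X = rng.normal(size=(350, 10))
                y = (rng.uniform(size=350) < expit(1.5 * X[:, 3])).astype(int)
                df = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
                m = pg.backward_select(df, y, alpha=0.157)
                hits += "f3" in m.feature_names
        assert hits >= 19


class TestMetrics:
    def test_confusion_metric_arithmetic(self):
        m = pg.confusion_metrics(95, 6, 94, 5)
        assert m["sensitivity"] == pytest.approx(95.0)
        assert m["specificity"] == pytest.approx(94.0)
        assert m["accuracy"] == pytest.approx(94.5)
        perfect = pg.confusion_metrics(10, 0, 10, 0)
        assert all(v == 100.0 for v in perfect.values())

    def test_random_counts_match_direct_arithmetic(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = pg.confusion_metrics(tp, fp, tn, fn)
            assert m["ppv"] == pytest.approx(100 * tp / (tp + fp))
            assert m["npv"] == pytest.approx(100 * tn / (tn + fn))

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            pg.confusion_metrics(0, 0, 0, 0)

    def test_roc_auc_examples(self):
        assert pg.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])["auc"] == 1.0
        assert pg.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])["auc"] == pytest.approx(0.75)
        assert pg.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])["auc"] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            pg.roc_auc([0.5, 0.6], [1, 1])

    def test_auc_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert pg.roc_auc(scores, labels)["auc"] == pytest.approx(
                auc_pair_oracle(scores, labels), abs=1e-12)


class TestKfoldCv:
    def test_partition_covers_each_sample_once(self):
        X, y = _toy_data(seed=8, n=105)
        rep = pg.kfold_cv(X, y, k=10, seed=0)
        assert rep.fold_assignment.min() == 0
        assert rep.fold_assignment.max() == 9
        assert np.bincount(rep.fold_assignment).sum() == 105

    def test_separable_data_perfect_metrics(self):
        x = np.concatenate([np.full(50, 5.0), np.full(50, -5.0)])
        x += np.linspace(0, 0.1, 100)  # break exact ties
        y = np.concatenate([np.ones(50), np.zeros(50)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pg.kfold_cv(pd.DataFrame({"x": x}), y, k=10, seed=1)
        assert rep.averaged["auc"] == 1.0
        assert rep.averaged["sensitivity"] == 100.0
        assert rep.averaged["specificity"] == 100.0

    def test_same_seed_reproducible_different_seed_stable(self):
        X, y = _toy_data(seed=9, n=300, beta=(3.0, -2.0))
        a = pg.kfold_cv(X, y, k=10, seed=42)
        b = pg.kfold_cv(X, y, k=10, seed=42)
        assert a.averaged == b.averaged
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        c = pg.kfold_cv(X, y, k=10, seed=43)
        assert not np.array_equal(a.fold_assignment, c.fold_assignment)
        assert abs(a.averaged["auc"] - c.averaged["auc"]) < 0.05

    def test_averaged_is_mean_of_folds(self):
        X, y = _toy_data(seed=10)
        rep = pg.kfold_cv(X, y, k=5, seed=2)
        for mname in ("auc", "accuracy"):
            vals = [f[mname] for f in rep.per_fold if not np.isnan(f[mname])]
            assert rep.averaged[mname] == pytest.approx(np.mean(vals))
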