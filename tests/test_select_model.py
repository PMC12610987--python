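import numpy as np
import pandas as pd
import pytest
from xgboost import XGBClassifier

from breathsig.select_model import (
    DEFAULT_LEARNER_PARAMS, ConfigError, CVError, EvaluationError, SplitError,
    consensus_features, evaluate, resample_importance, split_data,
    top_percent_features, tune_and_fit,
)

FAST = {"n_estimators": 30, "max_depth": 2}


class TestSplit:
    def test_balanced_split_counts(self):
        labels = np.array(["pos"] * 50 + ["neg"] * 50)
        ids = np.arange(100)
        train, test = split_data(ids, labels, 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30
        assert np.sum(labels[train] == "pos") == 35
        assert np.sum(labels[test] == "pos") == 15
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_reproducible_from_seed(self):
        labels = np.array(["a", "b"] * 20)
        t1, _ = split_data(np.arange(40), labels, seed=3)
        t2, _ = split_data(np.arange(40), labels, seed=3)
        np.testing.assert_array_equal(t1, t2)

    def test_singleton_stratum_rejected(self):
        labels = np.array(["a"] * 10 + ["b"])
        with pytest.raises(SplitError, match="singleton"):
            split_data(np.arange(11), labels)


def _planted_matrix(n=60, n_noise=50, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, size=(n, n_noise + 1))
    X[:, 0] += shift * y
    cols = [50.0] + sorted(rng.uniform(60, 300, n_noise).tolist())
    return pd.DataFrame(X, columns=cols), pd.Series(y)


class TestResampleImportance:
    def test_planted_feature_ranks_first(self):
        X, y = _planted_matrix()
        imp = resample_importance(X, y, n_iter=200, seed=1, learner_params=FAST)
        assert imp.idxmax() == 50.0

    def test_deterministic_given_seed(self):
        X, y = _planted_matrix()
        i1 = resample_importance(X, y, n_iter=10, seed=5, learner_params=FAST)
        i2 = resample_importance(X, y, n_iter=10, seed=5, learner_params=FAST)
        pd.testing.assert_series_equal(i1, i2)

    def test_permuted_labels_give_no_dominant_feature(self):
        """Under the null no feature should be selected far above chance."""
        X, y = _planted_matrix(shift=0.0)
        rng = np.random.default_rng(7)
        top_hits = {}
        for rep in range(20):
            yp = pd.Series(rng.permutation(y.to_numpy()))
            imp = resample_importance(X, yp, n_iter=10, seed=rep, learner_params=FAST)
            top = imp.idxmax()
            top_hits[top] = top_hits.get(top, 0) + 1
        # 51 features, 20 null draws: no feature tops the ranking half the time
        assert max(top_hits.values()) <= 10

    def test_invalid_iteration_count_rejected(self):
        X, y = _planted_matrix()
        with pytest.raises(ConfigError):
            resample_importance(X, y, n_iter=0)

    def test_single_class_rejected(self):
        X, _ = _planted_matrix()
        with pytest.raises(ConfigError):
            resample_importance(X, np.zeros(len(X)), n_iter=5)


class TestConsensus:
    def _imp(self, order):
        return pd.Series(np.linspace(1.0, 0.1, len(order)), index=order)

    def test_identical_rankings_give_full_topk(self):
        feats = list(np.round(np.linspace(50, 200, 40), 3))
        sel = consensus_features(self._imp(feats), self._imp(feats), top_k=30)
        assert len(sel.consensus_features) == 30
        assert sel.consensus_features == sorted(feats[:30])

    def test_disjoint_top_lists_warn_and_return_empty(self):
        a = list(np.round(np.linspace(50, 99, 40), 3))
        b = list(np.round(np.linspace(100, 200, 40), 3))
        both = a + b
        imp_a = pd.Series([1.0] * 40 + [0.0] * 40, index=both)
        imp_b = pd.Series([0.0] * 40 + [1.0] * 40, index=both)
        with pytest.warns(UserWarning, match="disjoint"):
            sel = consensus_features(imp_a, imp_b, top_k=30)
        assert sel.consensus_features == []

    def test_consensus_subset_of_each_ranked_list(self, small_cohort):
        cohort, mats = small_cohort
        from breathsig.features import filter_model_features

        sub = cohort[cohort.group.isin(["asthma", "control"])]
        y = (sub.group == "asthma").astype(int)
        imps = {m: resample_importance(
            filter_model_features(mats[m]).values.loc[sub.index], y,
            n_iter=25, seed=1, learner_params=FAST) for m in ("forced", "tidal")}
        sel = consensus_features(imps["forced"], imps["tidal"], top_k=30)
        assert set(sel.consensus_features) <= set(sel.ranked_lists["forced"])
        assert set(sel.consensus_features) <= set(sel.ranked_lists["tidal"])
        assert all(len(l) <= 30 for l in sel.ranked_lists.values())

    def test_ties_break_toward_lower_mz(self):
        feats = [100.0, 50.0, 75.0]
        imp = pd.Series([1.0, 1.0, 1.0], index=feats)
        sel = consensus_features(imp, imp, top_k=2)
        assert sel.ranked_lists["forced"] == [50.0, 75.0]

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ConfigError):
            consensus_features(pd.Series([1.0], index=[50.0]),
                               pd.Series([1.0], index=[60.0]))

    def test_top_percent_rule(self):
        imp = pd.Series(np.arange(100, 0, -1, dtype=float), index=np.arange(100.0))
        assert len(top_percent_features(imp, 10.0)) == 10
        assert top_percent_features(imp, 10.0)[0] == 0.0


class TestTuneAndFit:
    def test_separable_data_reaches_perfect_cv_auc(self):
        X, y = _planted_matrix(n=40, n_noise=5, shift=10.0)
        model = tune_and_fit(X, y, cv_folds=5, seed=0,
                             param_grid={"max_depth": [2], "n_estimators": [30]})
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, model.predict_proba(X.to_numpy())[:, 1]) == 1.0

    def test_same_seed_same_hyperparameters(self):
        X, y = _planted_matrix(n=40, n_noise=10, shift=1.0)
        grid = {"max_depth": [2, 3], "n_estimators": [20, 40]}
        m1 = tune_and_fit(X, y, cv_folds=3, param_grid=grid, seed=4)
        m2 = tune_and_fit(X, y, cv_folds=3, param_grid=grid, seed=4)
        assert m1.get_params()["max_depth"] == m2.get_params()["max_depth"]
        assert m1.get_params()["n_estimators"] == m2.get_params()["n_estimators"]

    def test_class_too_small_for_folds_rejected(self):
        X, y = _planted_matrix(n=8, n_noise=3)
        with pytest.raises(CVError):
            tune_and_fit(X, y, cv_folds=5)


class TestEvaluate:
    def _fitted(self, X, y):
        m = XGBClassifier(**{**DEFAULT_LEARNER_PARAMS, **FAST, "random_state": 0})
        m.fit(X.to_numpy(), y)
        return m

    def test_perfect_separation_metrics(self):
        class Stub:
            def predict_proba(self, X):
                p = np.array([0.9, 0.8, 0.1, 0.2])
                return np.column_stack([1 - p, p])

        X = pd.DataFrame(np.zeros((4, 1)), columns=[50.0])
        rep = evaluate(Stub(), X, [1, 1, 0, 0])
        assert rep.auc == 1.0 and rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.ppv == 1.0 and rep.npv == 1.0

    def test_threshold_tie_counts_as_positive(self):
        class Stub:
            def predict_proba(self, X):
                return np.full((4, 2), 0.5)

        X = pd.DataFrame(np.zeros((4, 1)), columns=[50.0])
        rep = evaluate(Stub(), X, [1, 1, 0, 0])
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_single_class_labels_rejected(self):
        X, y = _planted_matrix(n=10, n_noise=2)
        with pytest.raises(EvaluationError):
            evaluate(self._fitted(X, y), X, np.ones(10))

    def test_loo_aggregates_before_metrics(self):
        X, y = _planted_matrix(n=30, n_noise=3, shift=6.0)
        base = XGBClassifier(**{**DEFAULT_LEARNER_PARAMS, **FAST, "random_state": 0})
        rep = evaluate(base, X, y, scheme="loo")
        assert rep.cv_scheme == "loo"
        assert rep.n_train == 29 and rep.n_test == 30
        assert rep.auc > 0.9  # strongly separable data survives LOO


class TestNullCalibration:
    def test_held_out_auc_centred_on_chance_under_permutation(self):
        """Permuting labels destroys the signal: mean held-out AUC ~ 0.5."""
        X, y = _planted_matrix(n=80, n_noise=30, shift=3.0, seed=11)
        rng = np.random.default_rng(99)
        aucs = []
        for rep in range(20):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=X.index)
            tr, te = split_data(X.index.to_numpy(), yp.to_numpy(), 0.7, seed=rep)
            model = XGBClassifier(**{**DEFAULT_LEARNER_PARAMS, **FAST,
                                     "random_state": rep})
            model.fit(X.loc[tr].to_numpy(), yp.loc[tr])
            aucs.append(evaluate(model, X.loc[te], yp.loc[te]).auc)
        assert 0.45 <= float(np.mean(aucs)) <= 0.55


class TestNoLeakage:
    def test_selection_depends_only_on_training_rows(self):
        X, y = _planted_matrix(n=60, n_noise=20, shift=2.0, seed=3)
        tr = np.arange(40)
        imp_a = resample_importance(X.iloc[tr], y.iloc[tr], n_iter=15, seed=9,
                                    learner_params=FAST)
        # corrupt only the held-out rows: training-side selection must not move
        X2 = X.copy()
        X2.iloc[40:] = 1e6
        imp_b = resample_importance(X2.iloc[tr], y.iloc[tr], n_iter=15, seed=9,
                                    learner_params=FAST)
        pd.testing.assert_series_equal(imp_a, imp_b)
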