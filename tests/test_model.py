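import numpy as np
import pandas as pd
import pytest

from gliomics.model import (
    GBTModelSpec,
    MetricError,
    NestedLOOCVClassifier,
    PartitionError,
    RecursiveFeatureSelector,
    auc_mann_whitney,
    evaluate_binary,
    final_feature_set,
    hand_till_auc,
    multiclass_metrics,
    rf_importance_ranking,
    run_repetitions,
    stratified_partition,
    summarize_runs,
    train_gbt,
)


def brute_force_auc(scores, labels):
    wins = ties = total = 0
    for sp, yp in zip(scores, labels):
        if not yp:
            continue
        for sn, yn in zip(scores, labels):
            if yn:
                continue
            total += 1
            wins += sp > sn
            ties += sp == sn
    return (wins + 0.5 * ties) / total


class TestMetrics:
    @pytest.mark.parametrize("seed", range(30))
    def test_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # ties likely
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_worked_example(self):
        m = evaluate_binary([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert m["auc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = evaluate_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (m["auc"], m["sensitivity"], m["specificity"]) == (1.0, 1.0, 1.0)

    def test_all_ties_give_half(self):
        assert auc_mann_whitney([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(MetricError):
            evaluate_binary([0.1, 0.9], [1, 1])


class TestMulticlass:
    def test_perfect_three_class(self):
        proba = np.eye(3)[np.array([0, 0, 1, 1, 2, 2])]
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        m = multiclass_metrics(proba, labels, ["a", "b", "c"])
        assert m["accuracy"] == 1.0 and m["multiclass_auc"] == 1.0
        assert all(v["sensitivity"] == 1.0 for v in m["per_class"].values())

    def test_random_scores_near_half(self, rng):
        ms = []
        for _ in range(50):
            proba = rng.dirichlet(np.ones(3), size=60)
            labels = np.repeat(["a", "b", "c"], 20)
            ms.append(hand_till_auc(proba, labels, ["a", "b", "c"]))
        assert 0.45 <= np.mean(ms) <= 0.55

    def test_missing_class_rejected(self):
        with pytest.raises(MetricError):
            multiclass_metrics(np.eye(3), np.array(["a", "a", "b"]), ["a", "b", "c"])


class TestPartition:
    def test_reference_cohort_split_sizes(self):
        ids = [f"c{i}" for i in range(108)]
        labels = np.array(["positive"] * 85 + ["negative"] * 23)
        p = stratified_partition(ids, labels, "IDH", 0.75, seed=1)
        assert (len(p.train_ids), len(p.test_ids)) == (81, 27)

    def test_small_balanced_split_is_exact(self):
        ids = [f"c{i}" for i in range(8)]
        labels = np.array(["positive"] * 4 + ["negative"] * 4)
        p = stratified_partition(ids, labels, train_fraction=0.75, seed=0)
        assert len(p.train_ids) == 6
        train_pos = sum(1 for i in p.train_ids if int(i[1:]) < 4)
        assert train_pos == 3

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(20)]
        labels = np.array(["positive"] * 8 + ["negative"] * 12)
        a = stratified_partition(ids, labels, seed=5)
        b = stratified_partition(ids, labels, seed=5)
        assert a.train_ids == b.train_ids

    def test_stratification_within_one_case(self):
        ids = [f"c{i}" for i in range(108)]
        labels = np.array(["positive"] * 91 + ["negative"] * 17)
        p = stratified_partition(ids, labels, seed=3)
        train_pos = sum(1 for i in p.train_ids if int(i[1:]) < 91)
        assert abs(train_pos / 81 - 91 / 108) <= 1 / 81 + 1e-9

    def test_tiny_class_rejected(self):
        with pytest.raises(PartitionError):
            stratified_partition(["a", "b", "c"], np.array(["p", "p", "n"]), seed=0)


class TestGBT:
    def test_separable_training_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] > 0, "positive", "negative")
        model = train_gbt(X, y, ["a", "b"], GBTModelSpec(seed=0))
        proba = model.predict_proba(X)[:, 1]
        assert auc_mann_whitney(proba, y == "positive") == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        aucs = []
        for s in range(20):
            X_tr, X_te = rng.normal(size=(40, 5)), rng.normal(size=(40, 5))
            y_tr, y_te = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
            if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
                continue
            model = train_gbt(X_tr, y_tr, list("abcde"), GBTModelSpec(seed=s))
            aucs.append(auc_mann_whitney(model.predict_proba(X_te)[:, 1], y_te == 1))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_positive_weighting_helps_minority_recall(self):
        rng = np.random.default_rng(3)
        recalls = {"weighted": [], "flat": []}
        for s in range(10):
            n = 100
            y = np.array([1] * 10 + [0] * 90)
            X = rng.normal(size=(n, 3)) + y[:, None] * 0.8
            X_te = rng.normal(size=(n, 3)) + y[:, None] * 0.8
            for key, w in (("weighted", None), ("flat", 1.0)):
                model = train_gbt(X, y, list("abc"), GBTModelSpec(seed=s, scale_pos_weight=w))
                pred = model.predict_proba(X_te)[:, 1] >= 0.5
                recalls[key].append((pred & (y == 1)).sum() / 10)
        assert np.mean(recalls["weighted"]) >= np.mean(recalls["flat"])

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            train_gbt(np.zeros((5, 2)), np.ones(5), None)


class TestRanking:
    def test_informative_features_rank_high(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(60, 100))
            y = rng.integers(0, 2, 60)
            X[:, 0] += 3.0 * y
            X[:, 1] -= 3.0 * y
            names = [f"f{i}" for i in range(100)]
            top5 = rf_importance_ranking(X, y, names, seed=s)[:5]
            hits += {"f0", "f1"} <= set(top5)
        assert hits >= 18  # >= 90%

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.integers(0, 2, 30)
        assert rf_importance_ranking(X, y, seed=4) == rf_importance_ranking(X, y, seed=4)

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(MetricError):
            rf_importance_ranking(rng.normal(size=(10, 3)), np.zeros(10))


class TestRecursiveSelection:
    def test_informative_features_recovered(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.normal(size=(24, 60)), columns=[f"f{i}" for i in range(60)])
            y = np.array(["positive"] * 12 + ["negative"] * 12)
            X.loc[y == "positive", "f0"] += 2.5
            X.loc[y == "positive", "f1"] -= 2.5
            sel = RecursiveFeatureSelector(seed=s).fit(X, y)
            hits += {"f0", "f1"} <= set(sel.selected_features_)
        assert hits >= 8  # >= 80%

    def test_candidate_grid_fully_evaluated(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 20)), columns=[f"f{i}" for i in range(20)])
        y = rng.integers(0, 2, 80)
        X.loc[y == 1, "f0"] += 2
        sel = RecursiveFeatureSelector(seed=0).fit(X, y)
        assert sorted(sel.inner_auc_by_size_) == [2, 3, 5, 7, 9, 11, 13, 15]

    def test_null_labels_near_chance(self):
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            X = pd.DataFrame(rng.normal(size=(24, 30)), columns=[f"f{i}" for i in range(30)])
            y = np.array(["positive"] * 12 + ["negative"] * 12)
            sel = RecursiveFeatureSelector(candidate_sizes=(2, 3, 5), seed=s).fit(X, y)
            aucs.append(sel.inner_auc_)
        # selection maximizes over candidate sizes, so the null level sits
        # above 0.5 by selection bias but far from a real signal
        assert np.mean(aucs) <= 0.85

    def test_invalid_candidate_sizes_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError):
            RecursiveFeatureSelector(candidate_sizes=(2, 4)).fit(X, rng.integers(0, 2, 20))


class TestFinalFeatureSet:
    def test_unique_maximizer(self):
        feats, flag = final_feature_set([(("a", "b", "c"), 0.9), (("d", "e"), 0.7)])
        assert feats == ["a", "b", "c"] and not flag

    def test_tied_sets_intersect(self):
        feats, flag = final_feature_set([(("a", "b", "c"), 0.9), (("b", "c", "d"), 0.9)])
        assert feats == ["b", "c"] and not flag

    def test_disjoint_ties_fall_back_to_smallest(self):
        feats, flag = final_feature_set([(("a", "b", "c"), 0.9), (("d", "e"), 0.9)])
        assert feats == ["d", "e"] and flag


class TestNestedLOOCV:
    def _toy(self, n=16, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 25)), columns=[f"f{i}" for i in range(25)])
        y = np.array(["positive", "negative"] * (n // 2))
        if informative:
            X.loc[y == "positive", "f0"] += 3.0
        return X, y

    def test_every_case_scored_once(self):
        X, y = self._toy()
        clf = NestedLOOCVClassifier(candidate_sizes=(2, 3), seed=0).fit(X, y)
        assert clf.oof_proba_.shape == (16, 2)
        assert np.isfinite(clf.oof_proba_).all()
        assert len(clf.fold_selections_) == 16

    def test_strong_signal_high_cv_auc(self):
        X, y = self._toy(n=20, seed=1)
        clf = NestedLOOCVClassifier(candidate_sizes=(2, 3), seed=1).fit(X, y)
        assert clf.cv_metrics_["auc"] >= 0.9

    def test_leakage_canary_not_selected(self):
        """A feature informative only on held-out rows must never be chosen."""
        X, y = self._toy(n=16, seed=2)
        X_test = X.iloc[12:].copy()
        y_test = y[12:]
        X_train, y_train = X.iloc[:12].copy(), y[:12]
        rng = np.random.default_rng(9)
        X_train["canary"] = rng.normal(size=len(X_train))  # noise on train rows
        X_test["canary"] = (y_test == "positive").astype(float)  # label on test rows
        clf = NestedLOOCVClassifier(candidate_sizes=(2, 3), seed=2).fit(X_train, y_train)
        assert "canary" not in clf.selected_features_
        m = clf.evaluate(X_test, y_test)
        assert m["auc"] >= 0.5  # the informative f0 drives the prediction

    def test_too_few_cases_rejected(self):
        X, y = self._toy(n=8)
        with pytest.raises(PartitionError):
            NestedLOOCVClassifier().fit(X, y)

    def test_three_class_fit_reports_hand_till_auc(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(15, 10)), columns=[f"f{i}" for i in range(10)])
        y = np.repeat(["IDHwt", "IDHmut-codel", "IDHmut-noncodel"], 5)
        X["f0"] += np.repeat([0.0, 3.0, 6.0], 5)
        clf = NestedLOOCVClassifier(candidate_sizes=(2, 3), seed=0).fit(X, y)
        assert {"accuracy", "multiclass_auc", "per_class"} <= set(clf.cv_metrics_)
        assert clf.predict_proba(X).shape == (15, 3)
        assert clf.cv_metrics_["multiclass_auc"] >= 0.8


class TestRepetitions:
    def _table(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 30)),
            index=[f"c{i}" for i in range(n)],
            columns=[f"MBM.WT.glcm.f{i}" if i < 5 else f"T1.WT.glcm.f{i}" for i in range(30)],
        )
        y = pd.Series(np.array(["positive", "negative"] * (n // 2)), index=X.index)
        X.loc[y == "positive", "MBM.WT.glcm.f0"] += 3.0
        X.loc[y == "positive", "T1.WT.glcm.f7"] += 1.0
        return X, y

    def test_repetition_count_drawn_from_range(self):
        X, y = self._table()
        res = run_repetitions(X, y, "IDH", n_reps=2, candidate_sizes=(2,), master_seed=7)
        assert len(res) == 2
        rng = np.random.default_rng(7)
        assert 10 <= rng.integers(10, 16) <= 15  # documented draw for n_range default

    def test_deterministic_given_master_seed(self):
        X, y = self._table()
        kw = dict(n_reps=2, candidate_sizes=(2,), master_seed=3)
        a = run_repetitions(X, y, "IDH", **kw)
        b = run_repetitions(X, y, "IDH", **kw)
        assert [r.test for r in a] == [r.test for r in b]
        assert [r.selected_features for r in a] == [r.selected_features for r in b]

    def test_without_fractal_drops_map_columns(self):
        X, y = self._table()
        res = run_repetitions(X, y, "IDH", "without_fractal", n_reps=1, candidate_sizes=(2,), master_seed=1)
        assert all(not f.startswith("MBM") for f in res[0].selected_features)

    def test_summary_schema(self):
        X, y = self._table()
        res = run_repetitions(X, y, "IDH", n_reps=2, candidate_sizes=(2,), master_seed=5)
        summary = summarize_runs(res)
        assert {"block", "metric", "n", "mean", "sd"} <= set(summary.columns)
        assert set(summary["block"]) == {"cv", "test"}
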