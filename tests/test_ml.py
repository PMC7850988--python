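"""Signature discovery: CV plans, Boruta, RFE, AUROC, permutation testing."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from perturbsig import (
    LogRatioMatrix,
    boruta_select,
    evaluate_cv,
    fit_final_signature,
    hand_till_auc,
    make_cv_plan,
    permutation_test_model,
    rfe_select,
)
from perturbsig.ml import _rfe_indices

FAST_RF = {"n_estimators": 60}


def _lr(values):
    d = values.shape[1]
    return LogRatioMatrix(values, [(f"T{j}", "ref") for j in range(d)], "ALR", "ref")


class TestCvPlan:
    def test_stratified_arithmetic(self):
        labels = np.array(["A", "B"] * 20)
        plan = make_cv_plan(labels, k=10, r=10, seed=0)
        assert len(plan.folds) == 100
        for _, _, test_idx in plan.folds:
            assert len(test_idx) == 4
            assert (labels[test_idx] == "A").sum() == 2

    def test_each_repeat_partitions_samples(self):
        labels = np.array(["A", "B"] * 15)
        plan = make_cv_plan(labels, k=5, r=3, seed=1)
        for rep in range(3):
            seen = np.concatenate([t for r, _, t in plan.folds if r == rep])
            assert sorted(seen) == list(range(30))

    def test_determinism(self):
        labels = np.array(["A", "B"] * 10)
        p1 = make_cv_plan(labels, 5, 2, seed=7)
        p2 = make_cv_plan(labels, 5, 2, seed=7)
        for (r1, f1, t1), (r2, f2, t2) in zip(p1.folds, p2.folds):
            assert (r1, f1) == (r2, f2) and np.array_equal(t1, t2)

    def test_many_classes_all_represented(self):
        labels = np.repeat([f"g{i}" for i in range(10)], 8)
        plan = make_cv_plan(labels, k=5, r=1, seed=0)
        for _, _, test_idx in plan.folds:
            assert len(set(labels[test_idx])) == 10

    def test_k_reduced_to_min_class_size(self, caplog):
        labels = np.array(["A"] * 20 + ["B"] * 3)
        plan = make_cv_plan(labels, k=10, r=1, seed=0)
        assert plan.k == 3

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="single member"):
            make_cv_plan(np.array(["A"] * 5 + ["rare"]), 2, 1, seed=0)


class TestBoruta:
    def test_planted_signal_selected(self, rng):
        n = 60
        y = np.array(["A", "B"]).repeat(n // 2)
        x = rng.normal(size=(n, 51))
        x[:, 17] = (y == "B").astype(float)  # perfect signal among 50 noise columns
        sel = boruta_select(_lr(x), y, FAST_RF, seed=3, max_iter=30)
        assert "T17/ref" in sel

    def test_all_noise_selects_nearly_nothing(self, rng):
        n = 60
        y = np.array(["A", "B"]).repeat(n // 2)
        hits = []
        for seed in range(5):
            x = rng.normal(size=(n, 20))
            sel = boruta_select(_lr(x), y, FAST_RF, seed=seed, max_iter=25)
            hits.append(len(sel))
        assert np.mean(hits) <= 1.0  # near-empty selections under the null

    def test_duplicated_informative_feature_tolerated(self, rng):
        n = 40
        y = np.array(["A", "B"]).repeat(n // 2)
        signal = (y == "B") + rng.normal(0, 0.1, n)
        x = np.column_stack([signal, signal, rng.normal(size=(n, 10))])
        sel = boruta_select(_lr(x), y, FAST_RF, seed=0, max_iter=30)
        assert {"T0/ref", "T1/ref"} & set(sel)

    def test_binary_only(self, rng):
        x = rng.normal(size=(9, 4))
        with pytest.raises(ValueError, match="binary"):
            boruta_select(_lr(x), np.repeat(["a", "b", "c"], 3))


class TestRfe:
    def test_planted_features_recovered(self, rng):
        n, d, planted = 100, 45, 5
        y = np.repeat([f"g{i}" for i in range(10)], n // 10)
        x = rng.normal(size=(n, d))
        centers = rng.normal(0, 2.0, size=(10, planted))
        for i, g in enumerate(sorted(set(y))):
            x[np.asarray(y) == g, :planted] += centers[i]
        sel = rfe_select(_lr(x), y, FAST_RF, seed=1)
        recovered = sum(f"T{j}/ref" in sel for j in range(planted))
        assert recovered >= 4

    def test_single_informative_survives(self, rng):
        n = 60
        y = np.array(["A", "B", "C"]).repeat(n // 3)
        x = rng.normal(size=(n, 12))
        x[:, 4] += 3.0 * (np.asarray(y) == "B") - 3.0 * (np.asarray(y) == "C")
        sel = rfe_select(_lr(x), y, FAST_RF, seed=2)
        assert "T4/ref" in sel

    def test_elimination_path_strictly_decreasing(self, rng):
        n = 40
        y = np.array(["A", "B"]).repeat(n // 2)
        x = rng.normal(size=(n, 25))
        sizes = []
        remaining = np.arange(25)
        while remaining.size > 1:
            sizes.append(remaining.size)
            n_drop = max(1, int(round(0.2 * remaining.size)))
            remaining = remaining[n_drop:]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        # and the implementation honors the same schedule end to end
        sel = _rfe_indices(x, y, seed=0, rf_params=FAST_RF)
        assert 1 <= sel.size <= 25

    def test_too_few_features_returned_as_is(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.array(["A", "B"]).repeat(10)
        assert sorted(rfe_select(_lr(x), y, FAST_RF, seed=0)) == ["T0/ref", "T1/ref"]


class TestAuroc:
    def test_binary_equals_mann_whitney(self, rng):
        y = rng.choice(["neg", "pos"], size=40, p=[0.5, 0.5])
        while len(set(y)) < 2:
            y = rng.choice(["neg", "pos"], size=40)
        scores = rng.normal(size=40)
        proba = np.column_stack([1 - scores, scores])
        got = hand_till_auc(y, proba, np.array(["neg", "pos"]))
        u = mannwhitneyu(scores[y == "pos"], scores[y == "neg"]).statistic
        assert got == pytest.approx(u / ((y == "pos").sum() * (y == "neg").sum()), abs=1e-12)

    def test_three_class_equals_mean_pairwise_brute_force(self, rng):
        y = np.repeat(["a", "b", "c"], 7)
        proba = rng.dirichlet(np.ones(3), size=21)
        classes = np.array(["a", "b", "c"])
        got = hand_till_auc(y, proba, classes)

        def auc_one_way(ci, cj):  # brute-force pair counting with half ties
            si = proba[y == ci, list(classes).index(ci)]
            sj = proba[y == cj, list(classes).index(ci)]
            wins = sum((a > b) + 0.5 * (a == b) for a in si for b in sj)
            return wins / (len(si) * len(sj))

        brute = np.mean(
            [
                0.5 * (auc_one_way(ci, cj) + auc_one_way(cj, ci))
                for ci, cj in itertools.combinations(classes, 2)
            ]
        )
        assert got == pytest.approx(brute, abs=1e-12)

    def test_perfect_ranking(self):
        y = np.array(["A"] * 5 + ["B"] * 5)
        proba = np.column_stack([np.r_[np.ones(5), np.zeros(5)], np.r_[np.zeros(5), np.ones(5)]])
        assert hand_till_auc(y, proba, np.array(["A", "B"])) == 1.0


class TestEvaluateCv:
    def test_separable_data_scores_one(self, rng):
        y = np.array(["A", "B"]).repeat(15)
        x = rng.normal(size=(30, 5))
        x[:, 0] += 8.0 * (y == "B")
        plan = make_cv_plan(y, 5, 1, seed=0)
        ev = evaluate_cv(_lr(x), y, plan, "none", FAST_RF, seed=0)
        assert ev.mean_auroc == pytest.approx(1.0)
        assert ev.pooled_auroc == pytest.approx(1.0)

    def test_null_features_score_near_half(self, rng):
        y = np.array(["A", "B"]).repeat(50)
        x = rng.normal(size=(100, 8))
        plan = make_cv_plan(y, 5, 2, seed=1)
        ev = evaluate_cv(_lr(x), y, plan, "none", FAST_RF, seed=1)
        assert 0.4 <= ev.mean_auroc <= 0.6

    def test_fold_internal_selection_does_not_leak(self, rng):
        # selection-leak bias would push null AUROC well above chance;
        # honest fold-internal Boruta keeps it near 0.5
        y = np.array(["A", "B"]).repeat(25)
        x = rng.normal(size=(50, 30))
        plan = make_cv_plan(y, 5, 1, seed=2)
        ev = evaluate_cv(
            _lr(x), y, plan, "boruta", FAST_RF, seed=2, selector_kwargs={"max_iter": 15}
        )
        assert 0.3 <= ev.mean_auroc <= 0.68


class TestPermutationTest:
    def test_add_one_floor_on_strong_signal(self, rng):
        y = np.array(["A", "B"]).repeat(12)
        x = rng.normal(size=(24, 4))
        x[:, 1] += 6.0 * (y == "B")
        plan = make_cv_plan(y, 4, 1, seed=0)
        obs, p, null = permutation_test_model(
            _lr(x), y, plan, "none", FAST_RF, n_perm=24, seed=0
        )
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1 / 25)  # zero exceedances: (0+1)/(24+1)
        assert p >= 1 / 25

    def test_invalid_n_perm(self, rng):
        y = np.array(["A", "B"]).repeat(6)
        plan = make_cv_plan(y, 3, 1, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_model(_lr(rng.normal(size=(12, 3))), y, plan, n_perm=0)


class TestFinalSignature:
    def test_group_means_match_brute_force(self, rng):
        y = np.repeat(["A", "B", "C"], 6)
        x = rng.normal(size=(18, 4))
        model = fit_final_signature(_lr(x), y, "none", FAST_RF, seed=0)
        for gi, g in enumerate(["A", "B", "C"]):
            brute = x[np.asarray(y) == g].mean(axis=0)
            np.testing.assert_allclose(model.group_means.loc[g].to_numpy(), brute, atol=1e-12)

    def test_single_sample_group_mean_is_itself(self, rng):
        y = np.array(["A"] * 6 + ["B"] * 6)
        groups = np.array(["gA"] * 6 + ["gB"] * 5 + ["solo"])
        x = rng.normal(size=(12, 3))
        model = fit_final_signature(_lr(x), y, "none", FAST_RF, seed=0, groups=groups)
        np.testing.assert_allclose(model.group_means.loc["solo"].to_numpy(), x[-1], atol=1e-12)

    def test_planted_strain_difference_recovered(self, rng):
        n, planted = 60, 6
        y = np.array(["A", "B"]).repeat(n // 2)
        x = rng.normal(size=(n, 30))
        shifts = np.array([2.5, -2.5, 2.5, -2.5, 2.5, -2.5])
        x[:, :planted] += np.outer((y == "B").astype(float), shifts)
        model = fit_final_signature(
            _lr(x), y, "boruta", FAST_RF, seed=4, selector_kwargs={"max_iter": 30}
        )
        recovered = sum(f"T{j}/ref" in model.selected_features for j in range(planted))
        assert recovered >= 4
        assert np.isfinite(model.importances).all()

    def test_bit_reproducible_given_seed(self, rng):
        y = np.array(["A", "B"]).repeat(10)
        x = rng.normal(size=(20, 8))
        m1 = fit_final_signature(_lr(x), y, "rfe", FAST_RF, seed=9)
        m2 = fit_final_signature(_lr(x), y, "rfe", FAST_RF, seed=9)
        assert m1.selected_features == m2.selected_features
        np.testing.assert_array_equal(m1.importances.to_numpy(), m2.importances.to_numpy())
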