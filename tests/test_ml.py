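"""Feature selection, prevalence-fixed splits, ridge logistic, nested CV."""

import numpy as np
import pandas as pd
import pytest

from tbmscreen.ml import (
    CVResult,
    FeatureMatrix,
    NestedCVConfig,
    SelectionMask,
    build_feature_matrix,
    compute_metrics,
    fit_ridge_logistic,
    make_prevalence_split,
    n_selected_features,
    rank_features_ftest,
    run_nested_cv,
    select_fraction,
    selection_frequency_map,
    tune_ridge_C,
    evaluate_vs_dt,
)


def pooled_t(x0, x1):
    n0, n1 = len(x0), len(x1)
    sp2 = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / (n0 + n1 - 2)
    return (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))


class TestFtestRanking:
    def test_f_equals_t_squared(self, rng):
        """Two-class ANOVA F is the square of the pooled two-sample t."""
        X = rng.normal(size=(20, 30))
        y = np.array([0] * 9 + [1] * 11)
        mask = rank_features_ftest(X, y)
        for j in range(30):
            t = pooled_t(X[y == 0, j], X[y == 1, j])
            assert mask.scores[j] == pytest.approx(t**2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_strongly_shifted_column_ranks_first(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 1000))
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 137] += 10.0  # 10 sigma shift
        mask = rank_features_ftest(X, y)
        assert mask.ranked_voxel_indices[0] == 137

    def test_identical_class_values_give_zero_f(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 5.0  # constant column: zero between-class variance
        y = np.array([0] * 5 + [1] * 5)
        mask = rank_features_ftest(X, y)
        assert mask.scores[1] == 0.0

    def test_ties_broken_by_ascending_index(self, rng):
        X = np.zeros((10, 4))
        y = np.array([0] * 5 + [1] * 5)
        mask = rank_features_ftest(X, y)
        assert list(mask.ranked_voxel_indices) == [0, 1, 2, 3]

    def test_single_sample_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            rank_features_ftest(X, np.array([0, 0, 0, 0, 1]))


class TestSelectFraction:
    def test_half_percent_of_a_653k_voxel_mask(self):
        assert n_selected_features(653230, 0.005) == 3266
        assert n_selected_features(653230, 0.0025) == 1633

    def test_full_fraction_keeps_all(self, rng):
        X = rng.normal(size=(10, 20))
        y = np.array([0] * 5 + [1] * 5)
        sel = select_fraction(rank_features_ftest(X, y), 1.0)
        assert len(sel.selected_indices) == 20

    def test_minimum_one_feature(self, rng):
        X = rng.normal(size=(10, 10))
        y = np.array([0] * 5 + [1] * 5)
        sel = select_fraction(rank_features_ftest(X, y), 0.005)
        assert len(sel.selected_indices) == 1

    def test_fraction_above_one_rejected(self, rng):
        X = rng.normal(size=(10, 10))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError):
            select_fraction(rank_features_ftest(X, y), 1.5)


class TestPrevalenceSplit:
    def test_forced_prevalence_counts(self, rng):
        ids = [f"s{i}" for i in range(100)]
        labels = [1] * 50 + [0] * 50
        train, test = make_prevalence_split(ids, labels, 0.2, 0.2, rng)
        assert len(test) == 20
        test_labels = [labels[ids.index(s)] for s in test]
        assert sum(test_labels) == 4
        assert len(train) == 80

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(40)]
        labels = [1] * 15 + [0] * 25
        a = make_prevalence_split(ids, labels, 0.2, 0.25, np.random.default_rng(3))
        b = make_prevalence_split(ids, labels, 0.2, 0.25, np.random.default_rng(3))
        assert a == b

    def test_disjoint_and_exact_over_random_configs(self):
        """100 random configurations: exact positive count, no overlap."""
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 100:
            n = int(rng.integers(20, 120))
            n_pos = int(rng.integers(5, n - 5))
            tf = float(rng.uniform(0.15, 0.35))
            rho = float(rng.uniform(0.1, 0.5))
            ids = [f"s{i}" for i in range(n)]
            labels = [1] * n_pos + [0] * (n - n_pos)
            try:
                train, test = make_prevalence_split(ids, labels, tf, rho, rng)
            except ValueError:
                continue
            n_test = round(tf * n)
            assert len(test) == n_test
            assert sum(labels[ids.index(s)] for s in test) == round(rho * n_test)
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) <= set(ids)
            n_checked += 1

    def test_unattainable_prevalence_reports_range(self, rng):
        ids = [f"s{i}" for i in range(20)]
        labels = [1] * 2 + [0] * 18
        with pytest.raises(ValueError, match="attainable prevalence range"):
            make_prevalence_split(ids, labels, 0.5, 0.9, rng)


class TestRidgeLogistic:
    def test_heavy_shrinkage_limit(self, rng):
        X = rng.normal(size=(40, 5))
        y = (rng.random(40) > 0.5).astype(int)
        y[0], y[1] = 0, 1  # both classes present
        model = fit_ridge_logistic(X, y, C=1e-8)
        assert np.linalg.norm(model.weights) < 1e-3

    def test_symmetric_1d_toy_threshold_at_zero(self):
        X = np.array([[-1.0]] * 10 + [[1.0]] * 10)
        y = np.array([0] * 10 + [1] * 10)
        model = fit_ridge_logistic(X, y, C=1.0)
        assert model.predict_proba(np.array([[0.0]]))[0] == pytest.approx(0.5, abs=1e-6)

    def test_gradient_of_objective_vanishes_at_optimum(self, rng):
        """Numerical check of the stated objective: sum losses + |w|^2/(2C)."""
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=30) > 0).astype(int)
        C = 0.7
        model = fit_ridge_logistic(X, y, C=C)
        Z = (X - model.mean_) / model.scale_
        w, b = model.weights, model.intercept
        p = 1.0 / (1.0 + np.exp(-(Z @ w + b)))
        grad_w = Z.T @ (p - y) + w / C
        grad_b = np.sum(p - y)
        assert np.linalg.norm(np.append(grad_w, grad_b)) < 1e-4

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            fit_ridge_logistic(X, np.array([0, 1]), C=1.0)


class TestTuneC:
    def make_separable(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 3))
        X[:, 0] = y * 4.0 - 2.0 + 0.1 * rng.normal(size=n)
        subjects = [f"s{i}" for i in range(n)]
        return X, y, subjects

    def test_grid_of_one_returned(self):
        X, y, subjects = self.make_separable()
        assert tune_ridge_C(X, y, subjects, [0.37]) == 0.37

    def test_tie_goes_to_smallest_c(self):
        X, y, subjects = self.make_separable()
        # all of these are large enough to separate -> perfect f1 everywhere
        best = tune_ridge_C(X, y, subjects, [1.0, 10.0, 100.0], rng=np.random.default_rng(0))
        assert best == 1.0

    def test_underfitting_small_c_not_chosen(self):
        # with a minority positive class, heavy shrinkage pushes every
        # probability to the (sub-0.5) prior -> zero f1; a larger C separates
        rng = np.random.default_rng(2)
        n = 30
        y = np.array(([0, 0, 1] * (n // 3)))
        X = rng.normal(size=(n, 3))
        X[:, 0] = y * 4.0 - 2.0 + 0.1 * rng.normal(size=n)
        subjects = [f"s{i}" for i in range(n)]
        best = tune_ridge_C(X, y, subjects, [1e-8, 1.0], rng=np.random.default_rng(1))
        assert best == 1.0


class TestMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        for v in m.as_dict().values():
            assert v == 1.0

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, np.full(4, 0.7))
        assert m.auc == 0.5

    def test_auc_matches_pair_counting_oracle(self, rng):
        """Rank-statistic AUC vs brute force over all pos-neg pairs."""
        y = (rng.random(200) > 0.6).astype(int)
        scores = np.round(rng.random(200), 2)  # induce ties
        m = compute_metrics(y, scores)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert m.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_no_predicted_positives_precision_zero(self):
        y = np.array([0, 0, 1, 1])
        with pytest.warns(RuntimeWarning, match="precision"):
            m = compute_metrics(y, np.array([0.1, 0.1, 0.2, 0.3]))
        assert m.precision == 0.0 and m.sensitivity == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1, 1, 1]), np.array([0.5, 0.6, 0.7]))

    def test_balanced_accuracy_identity_enforced(self):
        y = np.array([0, 0, 1, 1, 1])
        m = compute_metrics(y, np.array([0.2, 0.8, 0.4, 0.9, 0.95]))
        assert m.balanced_accuracy == pytest.approx(
            (m.sensitivity + m.specificity) / 2, abs=1e-12
        )


def synthetic_feature_matrix(
    n_subjects=30, n_pos=12, n_voxels=200, effect=2.0, maps_per_subject=2, seed=0
):
    """Toy feature matrix with a known informative voxel block."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for i in range(n_subjects):
        label = int(i < n_pos)
        for m in range(maps_per_subject):
            x = rng.normal(size=n_voxels)
            if label:
                x[:20] += effect
            rows.append(x)
            meta.append(
                {
                    "subject_id": f"s{i}",
                    "group": "PreAD" if label else "Ctrl",
                    "label": label,
                    "dt": float(rng.uniform(0.5, 4.0)),
                    "mean_age": float(rng.uniform(60, 85)),
                }
            )
    mask = np.zeros((10, 10, 2), dtype=bool)
    mask.ravel()[:n_voxels] = True
    return FeatureMatrix(X=np.asarray(rows), meta=pd.DataFrame(meta), mask=mask)


class TestNestedCV:
    def test_deterministic_under_seed(self):
        fm = synthetic_feature_matrix()
        cfg = NestedCVConfig(n_repeats=2, seed=11, feature_fraction=0.1)
        a = run_nested_cv(fm, cfg)
        b = run_nested_cv(fm, cfg)
        assert a.metrics.equals(b.metrics)
        assert a.weight_checksums == b.weight_checksums
        assert a.chosen_C == b.chosen_C

    def test_no_leakage_from_test_maps(self):
        """Corrupting held-out maps leaves every train-time artifact intact."""
        fm = synthetic_feature_matrix()
        cfg = NestedCVConfig(n_repeats=1, seed=4, feature_fraction=0.1)
        clean = run_nested_cv(fm, cfg)
        test_subjects = set(clean.scores["subject_id"])
        corrupted_rows = fm.meta["subject_id"].isin(test_subjects).to_numpy()
        X2 = fm.X.copy()
        X2[corrupted_rows] += 37.0
        fm2 = FeatureMatrix(X=X2, meta=fm.meta.copy(), mask=fm.mask)
        dirty = run_nested_cv(fm2, cfg)
        assert dirty.weight_checksums == clean.weight_checksums
        assert dirty.chosen_C == clean.chosen_C
        assert np.array_equal(
            dirty.selections[0].selected_indices, clean.selections[0].selected_indices
        )

    def test_full_fraction_single_repeat_equals_plain_ridge(self):
        fm = synthetic_feature_matrix()
        cfg = NestedCVConfig(
            n_repeats=1, seed=2, feature_fraction=1.0, C_grid=(0.5,)
        )
        result = run_nested_cv(fm, cfg)
        # reproduce by hand: same split, ridge on all voxels
        from tbmscreen.ml import _repeat_rng

        rng = _repeat_rng(cfg.seed, 0)
        subj = fm.subject_labels()
        train_ids, test_ids = make_prevalence_split(
            subj.index.to_numpy(), subj.to_numpy(), 0.2, 0.2, rng
        )
        in_train = fm.meta["subject_id"].isin(train_ids).to_numpy()
        in_test = fm.meta["subject_id"].isin(test_ids).to_numpy()
        model = fit_ridge_logistic(fm.X[in_train], fm.y[in_train], 0.5)
        scores = model.predict_proba(fm.X[in_test])
        m = compute_metrics(fm.y[in_test], scores)
        assert result.metrics["auc"][0] == pytest.approx(m.auc, abs=1e-12)
        assert result.scores["score"].to_numpy() == pytest.approx(scores, abs=1e-9)

    def test_metrics_bounded_and_identity_holds(self):
        fm = synthetic_feature_matrix(effect=0.5)
        result = run_nested_cv(fm, NestedCVConfig(n_repeats=5, seed=0, feature_fraction=0.1))
        vals = result.metrics[
            ["auc", "accuracy", "balanced_accuracy", "precision", "sensitivity", "specificity", "f1"]
        ].to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        ba = result.metrics["balanced_accuracy"].to_numpy()
        expected = (result.metrics["sensitivity"] + result.metrics["specificity"]).to_numpy() / 2
        assert ba == pytest.approx(expected, abs=1e-9)

    def test_monotone_degradation_with_noise(self):
        """More per-scan noise never helps the classifier (same seeds)."""
        from tbmscreen.simulate import EffectModel, simulate_cohort

        aucs = {}
        for sd in (0.2, 0.8):
            em = EffectModel(seed=6, scan_noise_sd=sd)
            fm = build_feature_matrix(simulate_cohort(em))
            res = run_nested_cv(fm, NestedCVConfig(n_repeats=8, seed=6))
            aucs[sd] = res.summary().loc["auc", "mean"]
        assert aucs[0.8] <= aucs[0.2] + 0.05

    def test_l1_embedded_selection_mode(self):
        fm = synthetic_feature_matrix()
        cfg = NestedCVConfig(
            n_repeats=2, seed=3, selection_method="l1_embedded", C_grid=(1.0,)
        )
        result = run_nested_cv(fm, cfg)
        assert all(len(s.selected_indices) >= 1 for s in result.selections)

    def test_summary_interval_contains_mean(self):
        fm = synthetic_feature_matrix(effect=1.0)
        res = run_nested_cv(fm, NestedCVConfig(n_repeats=6, seed=1, feature_fraction=0.1))
        for kind in ("percentile", "minmax"):
            s = res.summary(kind)
            assert np.all(s["lo"] <= s["mean"] + 1e-12)
            assert np.all(s["mean"] <= s["hi"] + 1e-12)


class TestEvaluateVsDt:
    def test_zero_threshold_equals_plain_cv(self):
        fm = synthetic_feature_matrix()
        cfg = NestedCVConfig(n_repeats=3, seed=9, feature_fraction=0.1)
        plain = run_nested_cv(fm, cfg)
        curves = evaluate_vs_dt(fm, cfg, [0.0])
        assert curves["mean_auc"][0] == pytest.approx(
            plain.summary().loc["auc", "mean"], abs=1e-12
        )

    def test_unsorted_thresholds_rejected(self):
        fm = synthetic_feature_matrix()
        with pytest.raises(ValueError):
            evaluate_vs_dt(fm, NestedCVConfig(n_repeats=1), [2.0, 1.0])

    def test_impossible_threshold_flagged_missing(self):
        fm = synthetic_feature_matrix()
        curves = evaluate_vs_dt(
            fm, NestedCVConfig(n_repeats=2, seed=0, feature_fraction=0.1), [0.0, 99.0]
        )
        assert not curves["missing"][0]
        assert curves["missing"][1]


class TestSelectionFrequency:
    def make_result(self, selected_per_repeat, n_cols=10):
        sels = [
            SelectionMask(
                ranked_voxel_indices=np.arange(n_cols),
                scores=np.zeros(n_cols),
                selected_fraction=0.1,
                selected_indices=np.asarray(idx),
            )
            for idx in selected_per_repeat
        ]
        return CVResult(
            metrics=pd.DataFrame({"auc": [1.0] * len(sels)}),
            chosen_C=[1.0] * len(sels),
            selections=sels,
            scores=pd.DataFrame(),
            weight_checksums=[""] * len(sels),
            config=NestedCVConfig(),
            n_repeats_requested=len(sels),
            n_repeats_valid=len(sels),
        )

    def test_always_and_never_selected(self):
        result = self.make_result([[0, 3], [0, 5]])
        mask = np.zeros((5, 2, 1), dtype=bool)
        mask.ravel()[:10] = True
        freq = selection_frequency_map(result, mask)
        flat = freq[mask]
        assert flat[0] == 1.0
        assert flat[3] == 0.5 and flat[5] == 0.5
        assert flat[1] == 0.0

    def test_geometry_mismatch_rejected(self):
        result = self.make_result([[0]])
        with pytest.raises(ValueError, match="geometry"):
            selection_frequency_map(result, np.ones((3, 3, 3), dtype=bool))
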