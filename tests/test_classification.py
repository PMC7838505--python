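import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import _oracles as oracles
from gliomanet.classification import (
    EvaluationResult,
    compare_auc_distributions,
    cross_hemisphere_validate,
    fdr_adjust,
    fit_mlr,
    outer_cv_evaluate,
    roc_auc,
    smote_oversample,
)
from gliomanet.feature_selection import FeatureTable, SelectionConfig


def make_table(X, y, age=None):
    return FeatureTable(
        X=X,
        feature_ids=[f"f{i}" for i in range(X.shape[1])],
        labels=y,
        subject_ids=[f"s{i}" for i in range(X.shape[0])],
        age=age,
    )


class TestSMOTE:
    def test_rh_imbalance_exactly_balanced(self, rng):
        X = rng.standard_normal((46, 8))
        y = np.array([1] * 14 + [0] * 32)
        Xb, yb = smote_oversample(X, y, seed=0)
        assert np.bincount(yb).tolist() == [32, 32]
        np.testing.assert_array_equal(Xb[:46], X)  # originals untouched

    def test_balanced_input_passthrough(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = smote_oversample(X, y, seed=1)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_synthetic_points_on_minority_segment(self, rng):
        # minority points collinear: x2 = 2 * x1 + 1
        x1 = np.linspace(0, 1, 5)
        minority = np.column_stack([x1, 2 * x1 + 1])
        majority = rng.standard_normal((12, 2)) + 10
        X = np.vstack([minority, majority])
        y = np.array([1] * 5 + [0] * 12)
        Xb, yb = smote_oversample(X, y, k_neighbors=3, seed=2)
        new = Xb[17:]
        np.testing.assert_allclose(new[:, 1], 2 * new[:, 0] + 1, atol=1e-12)
        assert new[:, 0].min() >= 0 and new[:, 0].max() <= 1  # convex hull

    def test_singleton_minority_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="minority"):
            smote_oversample(X, y)


class TestFitMLR:
    def test_monotone_probabilities_in_1d(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = (np.arange(10) >= 5).astype(int)
        model = fit_mlr(X, y, ["f0"])
        p = model.predict_proba(X)
        assert np.all(np.diff(p) > 0)

    def test_null_slopes_within_wald_bound(self, rng):
        n = 2000
        X = rng.standard_normal((n, 3))
        y = rng.integers(0, 2, size=n)
        model = fit_mlr(X, y, ["a", "b", "c"])
        # Wald SE from the inverse Fisher information at the fit
        Z = (X - X.mean(0)) / X.std(0)
        design = np.column_stack([np.ones(n), Z])
        mu = model.predict_proba(X)
        H = (design.T * (mu * (1 - mu))) @ design
        se = np.sqrt(np.diag(np.linalg.inv(H)))[1:]
        assert np.all(np.abs(model.coefficients) < 3 * se)

    def test_matches_irls_oracle(self, rng):
        n, p = 20, 3
        X = rng.standard_normal((n, p))
        logits = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        model = fit_mlr(X, y, list("abc"), ridge=1e-4)
        Z = (X - X.mean(0)) / X.std(0)
        beta = oracles.irls_logistic(Z, y, ridge=1e-4)
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-6)

    def test_zero_variance_feature_named(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="zv"):
            fit_mlr(X, y, ["ok", "zv"])


class TestROC:
    def test_perfect_ranking(self):
        points, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == 1.0
        assert (0.0, 1.0) in points

    def test_reversed_ranking(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([0, 0, 1, 1]))
        assert auc == 0.0

    def test_tied_scores_hand_count(self):
        _, auc = roc_auc(np.array([0.2, 0.4, 0.4, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.875)  # (1 + 0.5 + 1 + 1) / 4

    def test_equals_mann_whitney_on_random_fixtures(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.standard_normal(n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            ref = oracles.pairwise_auc(scores, labels)
            assert auc == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestAUCComparison:
    def test_identical_paired_samples(self):
        a = np.array([0.8, 0.9, 0.7])
        t, p = compare_auc_distributions(a, a.copy(), paired=True)
        assert (t, p) == (0.0, 1.0)

    def test_identical_two_sample(self):
        t, p = compare_auc_distributions(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_variance_textbook_fixture(self):
        a = np.array([0.9, 0.85, 0.88])
        b = np.array([0.6, 0.62, 0.58])
        t, p = compare_auc_distributions(a, b)
        # hand-computed pooled-variance t
        na, nb = 3, 3
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)


class TestFDR:
    def test_textbook_fixture(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(fdr_adjust(np.array([0.2])), [0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(fdr_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.1, 1.5]))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_stepup_oracle(self, seed):
        p = np.random.default_rng(seed).random(8)
        np.testing.assert_allclose(fdr_adjust(p), oracles.bh_adjust(p), atol=1e-12)


class TestEvaluationResult:
    def test_mean_sd_consistency(self):
        res = EvaluationResult.from_aucs([0.7, 0.8, 0.9], [], "validation")
        assert res.mean == pytest.approx(np.mean(res.aucs), abs=1e-12)
        assert res.sd == pytest.approx(np.std(res.aucs, ddof=1), abs=1e-12)

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError):
            EvaluationResult.from_aucs([0.5, 1.2], [], "train")


def planted_table(rng, n=40, f=150, n_signal=4, scale=2.0):
    X = rng.standard_normal((n, f))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    for j in range(n_signal):
        X[:, j] += scale * y
    age = 40 + 6 * y + 8 * rng.standard_normal(n)
    return make_table(X, y, age=age)


class TestOuterCV:
    CFG = SelectionConfig(ci_level=0.99, top_pct=0.10, n_repetitions=5, k_inner=5, seed=0)

    def test_signal_recovered_and_train_exceeds_validation(self, rng):
        table = planted_table(rng)
        ev = outer_cv_evaluate(table, self.CFG, cv_folds=5, seed=0)
        assert ev.validation.mean > 0.85
        assert ev.train.mean >= ev.validation.mean
        assert all("age" in feats for feats in ev.selected_features)

    def test_leakage_sentinel_label_permutation(self, rng):
        # permuting labels before the pipeline must kill validation AUC;
        # averaged over permutations since single small-n runs are noisy
        table = planted_table(rng)
        val_means, train_means = [], []
        for k in range(5):
            perm = rng.permutation(table.n_subjects)
            shuffled = FeatureTable(
                X=table.X, feature_ids=table.feature_ids, labels=table.labels[perm],
                subject_ids=table.subject_ids, age=table.age,
            )
            ev = outer_cv_evaluate(shuffled, self.CFG, cv_folds=5, seed=k)
            val_means.append(ev.validation.mean)
            train_means.append(ev.train.mean)
        assert abs(np.mean(val_means) - 0.5) < 0.15
        assert np.mean(train_means) > 0.6  # selection still overfits training folds

    def test_determinism(self, rng):
        table = planted_table(rng)
        a = outer_cv_evaluate(table, self.CFG, cv_folds=4, seed=3)
        b = outer_cv_evaluate(table, self.CFG, cv_folds=4, seed=3)
        np.testing.assert_array_equal(a.validation.aucs, b.validation.aucs)
        np.testing.assert_array_equal(a.models[0].coefficients, b.models[0].coefficients)


class TestCrossHemisphere:
    def test_missing_feature_named(self, rng):
        table = planted_table(rng)
        ev = outer_cv_evaluate(table, TestOuterCV.CFG, cv_folds=4, seed=0)
        other = FeatureTable(
            X=rng.standard_normal((20, 2)),
            feature_ids=["g0", "g1"],  # disjoint from the models' features
            labels=np.array([0] * 10 + [1] * 10),
            subject_ids=[f"o{i}" for i in range(20)],
            age=40 + rng.standard_normal(20),
        )
        with pytest.raises(ValueError, match="missing"):
            cross_hemisphere_validate(ev.models, other)

    def test_shuffled_labels_give_chance_transfer(self, rng):
        table = planted_table(rng)
        ev = outer_cv_evaluate(table, TestOuterCV.CFG, cv_folds=4, seed=0)
        other = planted_table(rng, n=36)
        shuffled = FeatureTable(
            X=other.X, feature_ids=other.feature_ids,
            labels=other.labels[rng.permutation(36)],
            subject_ids=other.subject_ids, age=other.age[rng.permutation(36)],
        )
        res = cross_hemisphere_validate(ev.models, shuffled)
        assert abs(res.mean - 0.5) < 0.2
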