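"""Iterative stability selection: splits, filters, Lasso candidates, counting."""

import numpy as np
import pandas as pd
import pytest

from radscore.io import FeatureTable, StandardizationParams, standardize
from radscore.selection import (
    FittedLinearScorer,
    SelectionConfig,
    SelectionResult,
    accept_candidate,
    compute_rs,
    drop_zero_variance,
    fit_lasso_cv,
    permutation_screen,
    redundancy_filter,
    run_iterations,
    select_robust_features,
    split_cohort,
    _lasso_alpha_grid,
)
from radscore.synthetic import generate_feature_table

from conftest import make_small_config


def balanced_table(rng, n=120, p=8, effect=0.0):
    labels = np.tile([0, 1], n // 2)
    x = rng.standard_normal((n, p))
    x[labels == 1, 0] += effect
    names = [f"glcm_feat{i:02d}" for i in range(1, p + 1)]
    return FeatureTable([f"s{i}" for i in range(n)], labels, pd.DataFrame(x, columns=names))


class TestSplit:
    def test_80_20_split_of_balanced_cohort(self, rng):
        t = balanced_table(rng)
        train, test = split_cohort(t, 0.8, rng)
        assert (train.n_samples, test.n_samples) == (96, 24)
        assert int(train.labels.sum()) == 48 and int(test.labels.sum()) == 12

    def test_65_35_split(self, rng):
        t = balanced_table(rng)
        train, test = split_cohort(t, 0.65, rng)
        assert (train.n_samples, test.n_samples) == (78, 42)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        t = balanced_table(rng, n=50)
        train, test = split_cohort(t, 0.7, rng)
        assert set(train.sample_ids) | set(test.sample_ids) == set(t.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_seed_determinism(self, rng):
        t = balanced_table(rng)
        a1, b1 = split_cohort(t, 0.6, 7)
        a2, b2 = split_cohort(t, 0.6, 7)
        assert a1.sample_ids == a2.sample_ids and b1.sample_ids == b2.sample_ids
        a3, _ = split_cohort(t, 0.6, 8)
        assert a3.sample_ids != a1.sample_ids

    def test_empty_stratum_rejected(self, rng):
        t = balanced_table(rng, n=4)
        with pytest.raises(ValueError):
            split_cohort(t, 0.95, rng)


class TestFilters:
    def test_planted_constants_removed_exactly(self):
        cfg = make_small_config(seed=3)
        t, truth = generate_feature_table(cfg, "derivation")
        retained = drop_zero_variance(t)
        assert set(t.feature_names) - set(retained) == set(truth.zero_variance_names)

    def test_near_constant_feature_retained(self, rng):
        t = balanced_table(rng, p=3)
        t.values.iloc[:, 0] = 1.0
        t.values.iloc[0, 0] = 1.0 + 1e-9
        assert t.feature_names[0] in drop_zero_variance(t)

    def test_duplicate_feature_resolved_to_one(self, rng):
        t = balanced_table(rng, p=4)
        t.values.iloc[:, 1] = t.values.iloc[:, 0]
        retained, log = redundancy_filter(t, 0.9, 0.05)
        assert len({t.feature_names[0], t.feature_names[1]} & set(retained)) == 1
        assert len(log) == 1

    def test_orthogonal_features_all_retained(self, rng):
        t = balanced_table(rng, p=6)
        retained, log = redundancy_filter(t, 0.9, 0.05)
        assert retained == t.feature_names and log == []

    def test_threshold_is_strict_at_r_0p9(self, rng):
        n = 100
        labels = np.tile([0, 1], 50)
        base = rng.standard_normal(n)
        strong = 0.95 * base + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        weak_target = 0.85
        weak = weak_target * base + np.sqrt(1 - weak_target**2) * rng.standard_normal(n)
        # force the empirical correlations to land on the intended sides of 0.9
        assert abs(np.corrcoef(base, strong)[0, 1]) > 0.9
        assert abs(np.corrcoef(base, weak)[0, 1]) < 0.9
        t = FeatureTable([f"s{i}" for i in range(n)], labels,
                         pd.DataFrame({"glcm_feat01": base, "glcm_feat02": strong,
                                       "glcm_feat03": weak}))
        retained, _ = redundancy_filter(t, 0.9, 0.05)
        assert "glcm_feat03" in retained
        assert len(retained) == 2

    def test_screen_keeps_shifted_and_removes_identical_feature(self, rng):
        t = balanced_table(rng, effect=2.0)
        # column 1: identical value pattern in both label groups
        t.values.iloc[:, 1] = np.tile([5.0, 5.0, 6.0, 6.0], 30)
        retained, pvals = permutation_screen(t, 0.05, 499, rng)
        assert t.feature_names[0] in retained
        assert t.feature_names[1] not in retained
        assert pvals[t.feature_names[0]] == pytest.approx(1 / 500)

    def test_screen_type_one_calibration_on_null_table(self, rng):
        n, p = 120, 2000
        labels = np.tile([0, 1], n // 2)
        t = FeatureTable([f"s{i}" for i in range(n)], labels,
                         pd.DataFrame(rng.standard_normal((n, p)),
                                      columns=[f"glcm_feat{i}" for i in range(p)]))
        retained, _ = permutation_screen(t, 0.05, 499, rng)
        rate = len(retained) / p
        se = np.sqrt(0.05 * 0.95 / p)
        assert abs(rate - 0.05) < 3 * se


class TestLasso:
    def test_grid_maximum_nulls_all_coefficients(self, rng):
        from sklearn.linear_model import Lasso

        t = balanced_table(rng, effect=1.0)
        (std,), _ = standardize(t)
        grid = _lasso_alpha_grid(std.matrix, std.labels.astype(float))
        m = Lasso(alpha=grid[0] * (1 + 1e-10)).fit(std.matrix, std.labels.astype(float))
        assert np.allclose(m.coef_, 0.0, atol=1e-8)
        assert m.intercept_ == pytest.approx(std.labels.mean())

    def test_strong_feature_gets_nonzero_coefficient(self, rng):
        t = balanced_table(rng, effect=2.0)
        (std,), params = standardize(t)
        scorer = fit_lasso_cv(std, cv_folds=10, seed=1, params=params)
        assert t.feature_names[0] in scorer.feature_names

    def test_fewer_samples_than_folds_rejected(self, rng):
        t = balanced_table(rng, n=8)
        with pytest.raises(ValueError):
            fit_lasso_cv(t, cv_folds=10, seed=0)


class TestComputeRS:
    @staticmethod
    def make_scorer(names, coefs, intercept):
        params = StandardizationParams(pd.Series(0.0, index=names), pd.Series(1.0, index=names))
        return FittedLinearScorer(list(names), np.asarray(coefs, float), intercept, params)

    def test_arithmetic_identity(self):
        t = FeatureTable(["a"], [1], pd.DataFrame({"f1": [1.0], "f2": [-1.0]}))
        scorer = self.make_scorer(["f1", "f2"], [0.5, 0.2], 0.1)
        assert compute_rs(scorer, t)[0] == pytest.approx(0.4)

    def test_zero_coefficients_give_constant_intercept(self, rng):
        t = balanced_table(rng, n=10)
        scorer = self.make_scorer(t.feature_names, np.zeros(8), 0.7)
        assert np.allclose(compute_rs(scorer, t), 0.7)

    def test_matches_dot_product_oracle(self, rng):
        t = balanced_table(rng, n=20)
        for _ in range(50):
            k = int(rng.integers(1, 9))
            names = list(rng.choice(t.feature_names, size=k, replace=False))
            coefs = rng.standard_normal(k)
            intercept = float(rng.standard_normal())
            scorer = self.make_scorer(names, coefs, intercept)
            expected = np.array([
                sum(t.values.loc[s, nm] * c for nm, c in zip(names, coefs)) + intercept
                for s in t.sample_ids
            ])
            assert np.allclose(compute_rs(scorer, t), expected, atol=1e-12)

    def test_missing_feature_named_in_error(self, rng):
        t = balanced_table(rng, n=10)
        scorer = self.make_scorer(["not_there"], [1.0], 0.0)
        with pytest.raises(KeyError, match="not_there"):
            compute_rs(scorer, t)


class TestAcceptance:
    def test_scorer_without_features_auto_rejected(self, rng):
        t = balanced_table(rng)
        scorer = TestComputeRS.make_scorer([], [], 0.5)
        rec = accept_candidate(scorer, t, t, SelectionConfig(n_permutations=99), rng)
        assert not rec.accepted and "no features" in rec.reason

    def test_uninformative_test_scores_rejected(self, rng):
        train = balanced_table(rng, effect=3.0)
        test = balanced_table(rng, effect=0.0)  # exchangeable scores on test
        scorer = TestComputeRS.make_scorer([train.feature_names[0]], [1.0], 0.0)
        rec = accept_candidate(scorer, train, test, SelectionConfig(n_permutations=199), rng)
        assert rec.test_rs_perm_p > 0.05
        assert not rec.accepted


class TestRunIterations:
    def test_zero_iterations_empty_result(self):
        cfg = make_small_config(seed=5)
        t, _ = generate_feature_table(cfg, "derivation")
        res = run_iterations(t, SelectionConfig(n_iterations=0, seed=1))
        assert res.total_candidates == 0 and res.records == []
        assert all(c == 0 for c in res.counts.values())

    def test_candidate_count_and_conservation(self):
        cfg = make_small_config(seed=5)
        t, _ = generate_feature_table(cfg, "derivation")
        res = run_iterations(t, SelectionConfig(n_iterations=4, n_permutations=99,
                                                min_count=5, seed=1))
        assert res.total_candidates == 28 and len(res.records) == 28
        assert sum(res.counts.values()) == sum(
            len(r.selected_feature_names) for r in res.records if r.accepted)

    def test_rerun_is_bit_identical(self):
        cfg = make_small_config(seed=5)
        t, _ = generate_feature_table(cfg, "derivation")
        sc = SelectionConfig(n_iterations=3, n_permutations=99, min_count=5, seed=2)
        r1 = run_iterations(t, sc)
        r2 = run_iterations(t, sc)
        assert r1.counts == r2.counts
        assert [(r.delong_p, r.test_rs_perm_p, r.accepted) for r in r1.records] == \
               [(r.delong_p, r.test_rs_perm_p, r.accepted) for r in r2.records]


class TestSelectRobust:
    def test_strictly_greater_than_threshold(self):
        res = SelectionResult({"A": 150, "B": 100, "C": 99}, [], 7000)
        assert select_robust_features(res, 100) == ["A"]

    def test_empty_counts(self):
        assert select_robust_features(SelectionResult({}, [], 0), 100) == []

    def test_raising_threshold_never_grows_selection(self, rng):
        counts = {f"f{i}": int(rng.integers(0, 300)) for i in range(40)}
        res = SelectionResult(counts, [], 7000)
        previous = None
        for mc in (0, 50, 100, 200, 299):
            chosen = set(select_robust_features(res, mc))
            if previous is not None:
                assert chosen <= previous
            previous = chosen
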