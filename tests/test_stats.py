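"""Evaluation-statistics primitives against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from radscore.stats import (
    auc_delong,
    calibration_bins,
    confusion_metrics,
    decision_curve,
    delong_compare,
    hosmer_lemeshow,
    permutation_test_scores,
    report_at_cutoff,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting with ties worth 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_matches_pair_counting_on_small_instances(self, rng):
        for trial in range(40):
            n = int(rng.integers(4, 31))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            auc, _, _ = auc_delong(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_trivial_cases(self):
        auc, var, ci = auc_delong([1, 2, 10, 11], [0, 0, 1, 1])
        assert auc == 1.0 and var == 0.0 and ci == (1.0, 1.0)
        assert auc_delong([3, 1, 2, 4], [0, 1, 0, 1])[0] == 0.5
        assert auc_delong([5.0] * 6, [0, 1, 0, 1, 0, 1])[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([1, 2, 3], [1, 1, 1])


class TestDeLongCompare:
    def test_curve_vs_itself_paired(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        z, p = delong_compare(scores, labels, scores, labels, paired=True)
        assert z == 0.0 and p == 1.0

    def test_unpaired_type_one_error_calibration(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.standard_normal(60) + np.repeat([0, 1], 30)
            b = rng.standard_normal(60) + np.repeat([0, 1], 30)
            y = np.repeat([0, 1], 30)
            _, p = delong_compare(a, y, b, y, paired=False)
            rejections += p < 0.05
        rate = rejections / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_paired_requires_matching_labels(self, rng):
        s = rng.standard_normal(10)
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            delong_compare(s, y, s[:8], y[:8], paired=True)


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_3v3(self, rng):
        values = np.array([1.3, 0.2, -0.5, 2.1, 1.8, 0.9])
        labels = np.array([1, 1, 1, 0, 0, 0])
        observed = abs(values[:3].mean() - values[3:].mean())
        count = 0
        for pos in itertools.combinations(range(6), 3):
            grp = np.zeros(6, bool)
            grp[list(pos)] = True
            stat = abs(values[grp].mean() - values[~grp].mean())
            count += stat >= observed - 1e-12
        exact = count / 20
        b = 40000
        p = permutation_test_scores(values, labels, b, rng)
        assert abs(p - exact) < 3 * math.sqrt(exact * (1 - exact) / b) + 1 / b

    def test_identical_groups_give_p_one(self, rng):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert permutation_test_scores(values, labels, 999, rng) == 1.0

    def test_large_shift_saturates_at_floor(self, rng):
        values = np.concatenate([np.zeros(60), np.full(60, 3.0)])
        labels = np.concatenate([np.zeros(60, int), np.ones(60, int)])
        assert permutation_test_scores(values, labels, 999, rng) == pytest.approx(1 / 1000)

    def test_rejects_zero_permutations(self, rng):
        with pytest.raises(ValueError):
            permutation_test_scores([1.0, 2.0], [0, 1], 0, rng)


class TestYouden:
    @staticmethod
    def sweep_oracle(scores, labels):
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, int)
        pos, neg = scores[labels == 1], scores[labels == 0]
        best = -2.0
        for c in np.concatenate([scores - 1e-9, scores + 1e-9,
                                 [scores.min() - 1, scores.max() + 1]]):
            j = (pos >= c).mean() + (neg < c).mean() - 1
            best = max(best, j)
        return best

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(40):
            n = int(rng.integers(6, 51))
            labels = (rng.random(n) < 0.5).astype(int)
            labels[:2] = [0, 1]
            scores = np.round(rng.standard_normal(n), 1)
            op = youden_cutoff(scores, labels)
            assert op.youden_j == pytest.approx(self.sweep_oracle(scores, labels), abs=1e-9)

    def test_separated_groups(self):
        op = youden_cutoff([0, 1, 10, 11], [0, 0, 1, 1])
        assert op.youden_j == 1.0 and 1 < op.cutoff < 10

    def test_constant_scores_degenerate(self):
        op = youden_cutoff([2.0] * 6, [0, 1, 0, 1, 0, 1])
        assert op.degenerate and op.youden_j == 0.0

    def test_tie_break_prefers_specificity(self):
        # cutoffs (sens, spec) = (1, .5) and (.5, 1) both give J = 0.5
        op = youden_cutoff([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert op.specificity >= op.sensitivity


class TestConfusionMetrics:
    def test_reported_suite_from_reconstructed_matrix(self):
        rep = confusion_metrics(tp=20, fn=19, fp=4, tn=35)
        assert rep.sensitivity == pytest.approx(0.513, abs=5e-4)
        assert rep.specificity == pytest.approx(0.897, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.705, abs=5e-4)
        assert rep.kappa == pytest.approx(0.410, abs=5e-4)
        assert rep.error_rate == pytest.approx(1 - rep.accuracy)
        assert rep.recall == rep.sensitivity

    def test_zero_denominators_reported_undefined(self):
        rep = confusion_metrics(tp=3, fn=1, fp=0, tn=0)
        assert math.isnan(rep.specificity)
        assert rep.sensitivity == 0.75
        rep2 = confusion_metrics(tp=0, fn=0, fp=1, tn=3)
        assert math.isnan(rep2.sensitivity) and math.isnan(rep2.f1)

    def test_kappa_equals_2acc_minus_1_for_balanced_classes(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 60))
            tp = int(rng.integers(0, m + 1))
            tn = int(rng.integers(0, m + 1))
            rep = confusion_metrics(tp=tp, fn=m - tp, fp=m - tn, tn=tn)
            if not math.isnan(rep.kappa):
                assert rep.kappa == pytest.approx(2 * rep.accuracy - 1, abs=1e-12)


class TestHosmerLemeshow:
    def test_zero_when_probabilities_match_frequencies(self):
        p, y = [], []
        for prob, k in ((0.2, 10), (0.5, 10), (0.8, 10)):
            p += [prob] * k
            y += [1] * int(prob * k) + [0] * (k - int(prob * k))
        stat, df, _ = hosmer_lemeshow(np.array(p), np.array(y), g=3)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_computed_toy(self):
        # 3 groups of 4; O = (1, 2, 4), E = (0.4, 2.0, 3.4)
        p = np.array([0.1] * 4 + [0.5] * 4 + [0.85] * 4)
        y = np.array([1, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 1])
        stat, df, _ = hosmer_lemeshow(p, y, g=3)
        expected = 0.0
        for obs, exp, ng in ((1, 0.4, 4), (2, 2.0, 4), (4, 3.4, 4)):
            expected += (obs - exp) ** 2 / (exp * (1 - exp / ng))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert df == 1

    def test_rejects_probabilities_outside_open_interval(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5, 0.7], [0, 1, 0], g=3)


class TestCalibrationBins:
    def test_manual_two_bin_aggregation(self):
        p = np.array([0.1, 0.2, 0.3, 0.35, 0.4, 0.6, 0.7, 0.8, 0.9, 0.95])
        y = np.array([0, 0, 1, 0, 0, 1, 1, 0, 1, 1])
        bins = calibration_bins(p, y, n_bins=2)
        assert len(bins) == 2
        mp, obs, cnt = bins[0]
        assert cnt == 5 and mp == pytest.approx(np.mean(p[:5])) and obs == pytest.approx(0.2)
        assert sum(b[2] for b in bins) == 10

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            calibration_bins([0.5, 0.6], [0, 1], n_bins=3)


class TestDecisionCurve:
    def test_reference_policies(self):
        p = np.array([0.1, 0.4, 0.6, 0.9] * 4)
        y = np.array([0, 0, 1, 1] * 4)
        prev = y.mean()
        dca = decision_curve(p, y, thresholds=[0.25, prev, 0.75])
        assert np.all(dca.treat_none == 0.0)
        i = list(dca.thresholds).index(prev)
        assert dca.treat_all[i] == pytest.approx(0.0, abs=1e-12)

    def test_eight_sample_hand_case(self):
        p = np.array([0.9, 0.8, 0.6, 0.3, 0.7, 0.2, 0.1, 0.4])
        y = np.array([1, 1, 0, 1, 0, 0, 0, 0])
        dca = decision_curve(p, y, thresholds=[0.25])
        # at t = 0.25: predicted positive p >= .25 -> {.9,.8,.6,.3,.7,.4}; TP = 3, FP = 3
        expected = 3 / 8 - (3 / 8) * (0.25 / 0.75)
        assert dca.net_benefit[0] == pytest.approx(expected, abs=1e-12)

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        p = y.astype(float) * 0.98 + 0.01
        dca = decision_curve(p, y, thresholds=np.arange(0.05, 1.0, 0.05))
        assert np.allclose(dca.net_benefit, y.mean())


class TestReportAtCutoff:
    def test_rates_recomputable_from_counts(self, rng):
        scores = rng.standard_normal(50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        rep = report_at_cutoff(scores, labels, 0.1)
        assert rep.tp + rep.fn == labels.sum()
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 50)
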