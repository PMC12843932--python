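import itertools

import numpy as np
import pytest

from lipodisc import (
    auroc,
    compare_distributions_ranksum,
    confusion_metrics,
    generate_latent_cohort,
    make_block_folds,
    make_subsample_index,
    rmsecv,
    select_lv_count,
    summarize_distribution,
)
from lipodisc.evaluation import MetricError


def labels_from_counts(t_sch, t_bd, f_sch, f_bd):
    labels = ["SCH"] * (t_sch + f_bd) + ["BD"] * (t_bd + f_sch)
    predicted = ["SCH"] * t_sch + ["BD"] * f_bd + ["BD"] * t_bd + ["SCH"] * f_sch
    return np.array(labels), np.array(predicted)


class TestConfusion:
    def test_hand_computed_example(self):
        labels, predicted = labels_from_counts(45, 40, 5, 10)
        counts, rec = confusion_metrics(labels, predicted)
        assert (counts.T_SCH, counts.T_BD, counts.F_SCH, counts.F_BD) == (45, 40, 5, 10)
        assert rec.accuracy == pytest.approx(0.85)
        assert rec.sensitivity == pytest.approx(0.8182, abs=1e-4)
        assert rec.specificity == pytest.approx(0.8889, abs=1e-4)
        assert rec.class_error == pytest.approx(0.1465, abs=1e-4)

    def test_perfect_and_inverted(self):
        labels, _ = labels_from_counts(3, 3, 0, 0)
        _, perfect = confusion_metrics(labels, labels)
        assert perfect.accuracy == perfect.sensitivity == perfect.specificity == 1.0
        assert perfect.class_error == 0.0
        inverted = np.where(labels == "SCH", "BD", "SCH")
        _, worst = confusion_metrics(labels, inverted)
        assert worst.accuracy == 0.0
        assert worst.class_error == 1.0

    def test_balanced_identity_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            t_sch = int(rng.integers(0, n + 1))
            t_bd = int(rng.integers(0, n + 1))
            labels, predicted = labels_from_counts(t_sch, t_bd, n - t_bd, n - t_sch)
            _, rec = confusion_metrics(labels, predicted)
            assert rec.accuracy == pytest.approx((rec.sensitivity + rec.specificity) / 2)
            assert rec.class_error == pytest.approx(1 - rec.accuracy)

    def test_absent_class_rejected(self):
        labels = np.array(["SCH", "SCH"])
        with pytest.raises(MetricError, match="both classes"):
            confusion_metrics(labels, labels)


class TestAuroc:
    def test_edge_cases(self):
        labels = np.array(["SCH", "SCH", "BD", "BD"])
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 1.0
        assert auroc(np.array([0.5, 0.5, 0.5, 0.5]), labels) == 0.5

    def test_hand_counted_pairs(self):
        scores = np.array([0.9, 0.6, 0.4, 0.7, 0.3, 0.2])
        labels = np.array(["SCH", "SCH", "SCH", "BD", "BD", "BD"])
        assert auroc(scores, labels) == pytest.approx(7 / 9)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n1, n0 = rng.integers(2, 8, size=2)
            scores = np.round(rng.random(n1 + n0), 1)  # forces ties
            labels = np.array(["SCH"] * n1 + ["BD"] * n0)
            pos, neg = scores[:n1], scores[n1:]
            wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            assert auroc(scores, labels) == pytest.approx(wins / (n1 * n0))

    def test_monotone_invariance_and_complement(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        labels = np.array(["SCH"] * 10 + ["BD"] * 10)
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a)
        assert auroc(-scores, labels) == pytest.approx(1 - a)


class TestRmsecv:
    def test_known_values(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert rmsecv(y, y) == 0.0
        assert rmsecv(y + 0.1, y) == pytest.approx(0.1)
        assert rmsecv(np.full(4, 0.5), y) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(MetricError, match="empty"):
            rmsecv(np.array([]), np.array([]))


class TestSummarize:
    def test_symmetric_and_right_tailed(self):
        assert summarize_distribution([1.0, 2.0, 3.0]).skewness == pytest.approx(0.0)
        assert summarize_distribution([1.0, 1.0, 1.0, 10.0]).skewness > 0

    def test_degenerate_flagged(self):
        s = summarize_distribution([2.0, 2.0, 2.0, 2.0])
        assert s.degenerate and s.skewness == 0.0

    def test_matches_hand_formula(self):
        """Adjusted Fisher-Pearson g1·sqrt(n(n-1))/(n-2) and the matching
        small-sample excess-kurtosis adjustment, written out directly."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            v = rng.normal(size=int(rng.integers(5, 40)))
            n = len(v)
            m = v.mean()
            m2 = ((v - m) ** 2).mean()
            m3 = ((v - m) ** 3).mean()
            m4 = ((v - m) ** 4).mean()
            g1 = m3 / m2**1.5
            skew_exp = g1 * np.sqrt(n * (n - 1)) / (n - 2)
            g2 = m4 / m2**2 - 3
            kurt_exp = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6)
            s = summarize_distribution(v)
            assert s.skewness == pytest.approx(skew_exp, abs=1e-10)
            assert s.excess_kurtosis == pytest.approx(kurt_exp, abs=1e-10)


class TestRankSum:
    def test_identical_samples_p_near_half(self):
        a = np.arange(30.0)
        _, p, sig = compare_distributions_ranksum(a, a.copy(), tail="right")
        assert 0.4 < p < 0.6
        assert not sig

    def test_exact_small_sample_matches_enumeration(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        _, p, _ = compare_distributions_ranksum(b, a, tail="right")
        # enumeration over all rank assignments of the pooled sample
        pooled = np.concatenate([a, b])
        obs = b.sum()
        stats_all = [
            sum(pooled[list(c)]) for c in itertools.combinations(range(4), 2)
        ]
        p_exact = np.mean([s >= obs for s in stats_all])
        assert p == pytest.approx(p_exact)
        assert p == pytest.approx(1 / 6)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            a = rng.normal(1.0, 1.0, 100)
            b = rng.normal(0.0, 1.0, 100)
            _, _, sig = compare_distributions_ranksum(b, a, tail="left", alpha=0.01)
            hits += sig
        assert hits >= 19


class TestLvSelection:
    def test_structured_data_selects_three_components(self):
        """One predictive + two structured orthogonal directions → mode 3."""
        table = generate_latent_cohort(seed=1)
        folds = make_block_folds(table, 5, seed=2)
        sub = make_subsample_index(table, folds, 2, 10, seed=3)
        best, votes = select_lv_count(table, sub, max_lv=8)
        assert best == 3
        assert votes[3] > sum(votes.values()) * 0.4

    def test_pure_noise_prefers_minimal_complexity(self):
        rng = np.random.default_rng(5)
        table = generate_latent_cohort(seed=5, delta=3.0, orth_sd=(0.0, 0.0), overlap=0.0)
        folds = make_block_folds(table, 5, seed=6)
        sub = make_subsample_index(table, folds, 1, 10, seed=7)
        best, votes = select_lv_count(table, sub, max_lv=6)
        assert best == 2

    def test_deterministic(self):
        table = generate_latent_cohort(seed=8)
        folds = make_block_folds(table, 5, seed=9)
        sub = make_subsample_index(table, folds, 1, 5, seed=10)
        assert select_lv_count(table, sub, max_lv=5) == select_lv_count(
            table, sub, max_lv=5
        )
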