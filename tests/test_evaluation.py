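"""ROC/AUC, bootstrap, operating point, DeLong, grouped CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsewave.evaluation import (
    bootstrap_auc_ci,
    cv_auc,
    delong_compare,
    evaluate_scores,
    optimal_operating_point,
    roc_auc,
)
from _oracles import delong_p_direct, pairwise_auc


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_worked_example_matches_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(0.75)
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels))

    def test_random_scores_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_ties_count_half(self):
        assert roc_auc([1, 1], [0, 1]) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_and_complement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.standard_normal(n), 1)  # induce ties
        labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
        auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert auc + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = bootstrap_auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                  B=200, seed=0)
        assert lo == 1.0 and hi == 1.0

    def test_same_seed_identical_interval(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        b = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        assert a == b

    def test_interval_brackets_point_estimate(self, rng):
        pos = rng.normal(1.0, 1.0, 80)
        neg = rng.normal(0.0, 1.0, 120)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(80, int), np.zeros(120, int)]
        lo, hi = bootstrap_auc_ci(scores, labels, B=1000, seed=1)
        auc = roc_auc(scores, labels)
        assert lo <= auc <= hi

    def test_width_shrinks_like_root_n(self):
        """Doubling the sample size should shrink the mean CI width by a
        factor near 1/sqrt(2)."""
        delta = 1.0
        widths = {}
        for n in (100, 200):
            ws = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                scores = np.r_[rng.normal(delta, 1, n), rng.normal(0, 1, n)]
                labels = np.r_[np.ones(n, int), np.zeros(n, int)]
                lo, hi = bootstrap_auc_ci(scores, labels, B=500, seed=seed)
                ws.append(hi - lo)
            widths[n] = np.mean(ws)
        ratio = widths[200] / widths[100]
        assert 0.6 <= ratio <= 0.85


class TestOperatingPoint:
    def test_perfect_separation(self):
        thr, sens, spec = optimal_operating_point([1, 2, 9, 10], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0 and 2 < thr < 9

    def test_worked_example_threshold_between_classes(self):
        thr, sens, spec = optimal_operating_point([1, 2, 3, 4], [0, 0, 1, 1])
        assert 2 < thr < 3
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_anti_predictive_flagged(self):
        with pytest.warns(RuntimeWarning, match="anti-predictive"):
            thr, sens, spec = optimal_operating_point([4, 3, 2, 1],
                                                      [0, 0, 1, 1])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_ties_resolve_toward_specificity(self):
        # two thresholds reach J = 0.5; the higher-specificity one wins
        scores = [1, 2, 3, 4]
        labels = [0, 1, 0, 1]
        thr, sens, spec = optimal_operating_point(scores, labels)
        assert spec == 1.0 and sens == 0.5


class TestDeLong:
    def test_self_comparison_is_exactly_one(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        auc_a, auc_b, p = delong_compare(scores, scores, labels)
        assert auc_a == auc_b and p == 1.0

    def test_monotone_transform_is_exactly_one(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, _, p = delong_compare(scores, np.tanh(scores) * 5 + 1, labels)
        assert p == 1.0

    def test_matches_structural_components_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 80
            labels = np.r_[np.ones(30, int), np.zeros(50, int)]
            base = rng.standard_normal(n) + labels
            sa = base + 0.3 * rng.standard_normal(n)
            sb = 0.7 * base + 0.5 * rng.standard_normal(n)
            auc_a, auc_b, p = delong_compare(sa, sb, labels)
            assert p == pytest.approx(delong_p_direct(sa, sb, labels),
                                      abs=1e-6)
            assert auc_a == pytest.approx(pairwise_auc(sa, labels))
            assert auc_b == pytest.approx(pairwise_auc(sb, labels))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2], [1, 2, 3], [0, 1])


def grouped_features(n_groups: int = 12, per_group: int = 3, m: int = 40,
                     delta: float = 3.0, seed: int = 0):
    """Pixel-vector cohort with a planted class difference and patient
    structure."""
    rng = np.random.default_rng(seed)
    X, y, g = [], [], []
    direction = rng.standard_normal(m)
    direction /= np.linalg.norm(direction)
    for i in range(n_groups):
        label = i % 2
        offset = rng.standard_normal(m)  # patient-level shift
        for _ in range(per_group):
            x = rng.standard_normal(m) + 0.5 * offset \
                + delta * label * direction
            X.append(x)
            y.append(label)
            g.append(f"P{i}")
    return np.asarray(X), np.asarray(y), np.asarray(g)


class TestCvAuc:
    def test_separable_cohort_scores_high(self):
        X, y, g = grouped_features(delta=4.0, seed=1)
        res = cv_auc(X, y, g, k=4, seed=0)
        assert res.mean_auc > 0.95

    def test_folds_partition_groups(self):
        X, y, g = grouped_features(seed=2)
        res = cv_auc(X, y, g, k=4, seed=0)
        assert set(res.fold_of_group) == set(g)
        # every group lands in exactly one validation fold
        assert len(res.fold_of_group) == len(np.unique(g))

    def test_same_seed_same_folds(self):
        X, y, g = grouped_features(seed=3)
        a = cv_auc(X, y, g, k=4, seed=9)
        b = cv_auc(X, y, g, k=4, seed=9)
        assert a.fold_of_group == b.fold_of_group
        assert a.fold_aucs == b.fold_aucs

    def test_too_few_groups_rejected(self):
        X, y, g = grouped_features(n_groups=3)
        with pytest.raises(ValueError):
            cv_auc(X, y, g, k=5)

    def test_shuffled_labels_near_chance(self):
        aucs = []
        for seed in range(8):
            X, y, g = grouped_features(n_groups=16, delta=3.0, seed=seed)
            rng = np.random.default_rng(seed)
            # permute labels at the patient level to break the signal
            uniq = np.unique(g)
            perm = dict(zip(uniq, rng.permutation(
                [y[g == u][0] for u in uniq])))
            y_null = np.array([perm[gi] for gi in g])
            aucs.append(cv_auc(X, y_null, g, k=4, seed=seed).mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1


def test_evaluate_scores_report_consistency(rng):
    pos = rng.normal(1.5, 1.0, 60)
    neg = rng.normal(0.0, 1.0, 90)
    scores = np.r_[pos, neg]
    labels = np.r_[np.ones(60, int), np.zeros(90, int)]
    rep = evaluate_scores(scores, labels, B=400, seed=2)
    assert rep.ci[0] <= rep.auc <= rep.ci[1]
    assert rep.n_pos == 60 and rep.n_neg == 90
    assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1
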