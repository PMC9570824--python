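"""Segment scoring, ROC/AUROC with DeLong intervals, Youden operating point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarsleep.eval_segment import (
    ClassificationMetrics,
    EvaluationError,
    delong_compare,
    evaluate_segments,
    roc_auroc,
    segment_score,
    segment_scores,
    youden_cutoff,
)


def brute_force_segment_score(track):
    """Oracle: max over all 10-frame windows of the window minimum."""
    best = -np.inf
    for i in range(len(track) - 9):
        best = max(best, min(track[i : i + 10]))
    return best


class TestSegmentScore:
    def test_flat_track(self):
        assert segment_score(np.full(60, 0.5)) == 0.5

    def test_ten_frame_plateau_fires(self):
        track = np.full(60, 0.1)
        track[10:20] = 0.9
        assert segment_score(track) == pytest.approx(0.9)

    def test_nine_frame_plateau_does_not_fire(self):
        track = np.full(60, 0.1)
        track[10:19] = 0.9
        assert segment_score(track) == pytest.approx(0.1)

    def test_wrong_length(self):
        with pytest.raises(EvaluationError):
            segment_score(np.zeros(5))

    @settings(deadline=None, max_examples=300)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force(self, seed):
        track = np.random.default_rng(seed).random(60)
        assert segment_score(track) == brute_force_segment_score(list(track))

    def test_vectorized_matches_scalar(self, rng):
        tracks = rng.random((50, 60))
        assert np.array_equal(
            segment_scores(tracks), [segment_score(t) for t in tracks]
        )


def brute_force_auroc(scores, labels):
    """Oracle: enumerate all positive-negative pairs, ties count half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        auc, (lo, hi) = roc_auroc(scores, labels)
        assert auc == 1.0 and hi == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auroc(np.full(10, 0.3), np.array([0, 1] * 5))
        assert auc == 0.5

    def test_hand_set_matches_pair_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.4])
        labels = np.array([0, 0, 1, 1, 1, 0])
        auc, _ = roc_auroc(scores, labels)
        assert auc == pytest.approx(brute_force_auroc(scores, labels))

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_random_sets_match_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 1)  # coarse grid to exercise ties
        labels = rng.integers(0, 2, n)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        auc, _ = roc_auroc(scores, labels)
        assert auc == pytest.approx(brute_force_auroc(scores, labels))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10**6), scale=st.floats(0.1, 5), power=st.floats(0.2, 3))
    def test_invariant_under_monotone_transform(self, seed, scale, power):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        a1, _ = roc_auroc(scores, labels)
        a2, _ = roc_auroc(scale * scores**power, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auroc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestYouden:
    def test_separated_scores_reach_j_of_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        cutoff, m = youden_cutoff(scores, labels)
        assert m.sensitivity.value == 1.0 and m.specificity.value == 1.0
        assert 0.2 < cutoff <= 0.8

    def test_hand_set_matches_exhaustive_sweep(self):
        scores = np.array([0.05, 0.2, 0.3, 0.35, 0.5, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        cutoff, _ = youden_cutoff(scores, labels)
        best_j, best_cut = -np.inf, None
        for cand in sorted(set(scores)):
            pred = scores >= cand
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            if sens + spec - 1 > best_j:
                best_j, best_cut = sens + spec - 1, cand
        assert cutoff == best_cut

    def test_tie_resolves_to_lower_cutoff(self):
        # J identical at 0.4 and 0.6; the lower cutoff must win
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        cutoff, _ = youden_cutoff(scores, labels)
        assert cutoff == 0.4

    def test_count_metrics_from_cohort_scale_counts(self):
        # sensitivity/specificity/accuracy arithmetic on realistic count
        # magnitudes (tens of thousands of segments)
        m = ClassificationMetrics.from_counts(tp=8289, fn=11135 - 8289,
                                              tn=19065, fp=23757 - 19065)
        assert m.sensitivity.value == pytest.approx(0.744, abs=5e-4)
        assert m.specificity.value == pytest.approx(0.803, abs=5e-4)
        assert m.accuracy.value == pytest.approx(0.784, abs=5e-4)
        assert m.sensitivity.ci[0] < m.sensitivity.value < m.sensitivity.ci[1]


class TestDelongCompare:
    def test_identical_samples_give_p_one(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert delong_compare(scores, labels, scores, labels) == pytest.approx(1.0)

    def test_separated_vs_random_rejects(self, rng):
        n = 200
        labels = np.concatenate([np.zeros(n // 2), np.ones(n // 2)]).astype(int)
        strong = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(3, 1, n // 2)])
        random_scores = rng.random(n)
        p = delong_compare(strong, labels, random_scores, labels)
        assert p < 0.01

    def test_bootstrap_oracle_agrees_on_rejection(self, rng):
        # unpaired bootstrap of the AUROC difference as an independent check
        n = 150
        labels = np.concatenate([np.zeros(n // 2), np.ones(n // 2)]).astype(int)
        a = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(2.0, 1, n // 2)])
        b = rng.random(n)
        p = delong_compare(a, labels, b, labels)
        boots = []
        for _ in range(300):
            ia = rng.integers(0, n, n)
            ib = rng.integers(0, n, n)
            la, lb = labels[ia], labels[ib]
            if la.all() or not la.any() or lb.all() or not lb.any():
                continue
            boots.append(
                brute_force_auroc(a[ia], la) - brute_force_auroc(b[ib], lb)
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert (lo > 0) or (hi < 0)  # bootstrap CI excludes zero...
        assert p < 0.05              # ...and DeLong rejects too

    def test_two_sided_p_is_symmetric(self, rng):
        labels = np.array([0] * 20 + [1] * 20)
        a = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
        b = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)])
        assert delong_compare(a, labels, b, labels) == pytest.approx(
            delong_compare(b, labels, a, labels)
        )


class TestGroupedEvaluation:
    def test_group_counts_partition_overall(self, rng):
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        groups = rng.choice(["normal", "mild", "moderate", "severe"], 400)
        res = evaluate_segments(scores, labels, groups)
        overall = res["Overall"]
        for metric in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            got_num = sum(getattr(res[g], metric).numerator for g in res if g != "Overall")
            got_den = sum(getattr(res[g], metric).denominator for g in res if g != "Overall")
            assert got_num == getattr(overall, metric).numerator
            assert got_den == getattr(overall, metric).denominator

    def test_cutoff_shared_across_groups(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        groups = rng.choice(["a", "b"], 100)
        res = evaluate_segments(scores, labels, groups)
        assert res["a"].cutoff == res["Overall"].cutoff == res["b"].cutoff
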