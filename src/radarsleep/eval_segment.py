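"""Per-segment classification evaluation.

A 60-s segment's *abnormal score* is derived from its 1-Hz abnormal
probability track the same way the reference labeling works: it is the
minimum threshold at which the track still shows 10 consecutive
above-threshold seconds — equivalently the maximum over all 10-frame
windows of the within-window minimum.  Scored segments are then evaluated
with ROC/AUROC (DeLong confidence intervals), the Youden-index operating
point, and the usual count-based confusion metrics with Wilson intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

SCORE_WINDOW_S = 10


class EvaluationError(ValueError):
    pass


def segment_score(abnormal_track_60: np.ndarray) -> float:
    """Max-over-windows-of-min score of one 60-frame abnormal track."""
    track = np.asarray(abnormal_track_60, dtype=float)
    if track.ndim != 1 or track.size < SCORE_WINDOW_S:
        raise EvaluationError(
            f"expected a 1-D track of >= {SCORE_WINDOW_S} frames, got {track.shape}"
        )
    wins = np.lib.stride_tricks.sliding_window_view(track, SCORE_WINDOW_S)
    return float(wins.min(axis=1).max())


def segment_scores(abnormal_tracks: np.ndarray) -> np.ndarray:
    """Vectorized ``segment_score`` over an (n, 60) array of tracks."""
    tracks = np.asarray(abnormal_tracks, dtype=float)
    wins = np.lib.stride_tricks.sliding_window_view(tracks, SCORE_WINDOW_S, axis=1)
    return wins.min(axis=2).max(axis=1)


# ---------------------------------------------------------------------------
# AUROC with DeLong variance
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUROC plus the DeLong structural components (V10, V01)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise EvaluationError("need both classes present to compute AUROC")
    rank_all = _midrank(np.concatenate([pos, neg]))
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return auc, v10, v01


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def roc_auroc(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUROC (Mann-Whitney rank statistic, ties counted half) with the
    DeLong 95% confidence interval."""
    auc, v10, v01 = _delong_components(scores, labels)
    se = float(np.sqrt(_delong_var(v10, v01)))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(auc), (max(0.0, auc - z * se), min(1.0, auc + z * se))


def delong_compare(
    scores_a: np.ndarray,
    labels_a: np.ndarray,
    scores_b: np.ndarray,
    labels_b: np.ndarray,
) -> float:
    """Two-sided p-value for an unpaired AUROC difference.

    Intended for comparing disjoint participant groups; the variance of
    the difference is the sum of the two DeLong variances.
    """
    auc_a, v10a, v01a = _delong_components(scores_a, labels_a)
    auc_b, v10b, v01b = _delong_components(scores_b, labels_b)
    var = _delong_var(v10a, v01a) + _delong_var(v10b, v01b)
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# operating point and count metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricValue:
    value: float
    numerator: int
    denominator: int
    ci: tuple[float, float]

    @classmethod
    def from_counts(cls, numerator: int, denominator: int) -> "MetricValue":
        """Ratio metric with a Wilson 95% binomial interval."""
        if denominator == 0:
            return cls(float("nan"), 0, 0, (float("nan"), float("nan")))
        lo, hi = proportion_confint(numerator, denominator, method="wilson")
        return cls(numerator / denominator, numerator, denominator, (lo, hi))


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion metrics at one cutoff, each with counts and a Wilson CI."""

    cutoff: float
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, tn: int, fp: int, cutoff: float = float("nan"),
        auroc: float | None = None, auroc_ci: tuple[float, float] | None = None,
    ) -> "ClassificationMetrics":
        return cls(
            cutoff=cutoff,
            sensitivity=MetricValue.from_counts(tp, tp + fn),
            specificity=MetricValue.from_counts(tn, tn + fp),
            ppv=MetricValue.from_counts(tp, tp + fp),
            npv=MetricValue.from_counts(tn, tn + fn),
            accuracy=MetricValue.from_counts(tp + tn, tp + fn + tn + fp),
            auroc=auroc,
            auroc_ci=auroc_ci,
        )


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) with a segment predicted abnormal when score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= cutoff
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return tp, fn, tn, fp


def youden_cutoff(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, ClassificationMetrics]:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    Candidate cutoffs are the observed score values (a segment fires when
    its score is >= the cutoff); ties resolve to the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise EvaluationError("need both classes present for a Youden cutoff")
    cands = np.unique(scores)
    # sens(θ) and spec(θ) for θ descending via cumulative counts
    best_j, best_cut = -np.inf, cands[0]
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    for cut in cands:  # ascending, so later candidates only win strictly
        pred = scores >= cut
        j = np.sum(pred & labels) / n_pos + np.sum(~pred & ~labels) / n_neg - 1.0
        if j > best_j:
            best_j, best_cut = j, cut
    auc, ci = roc_auroc(scores, labels)
    tp, fn, tn, fp = confusion_counts(scores, labels, best_cut)
    return float(best_cut), ClassificationMetrics.from_counts(
        tp, fn, tn, fp, cutoff=float(best_cut), auroc=auc, auroc_ci=ci
    )


def evaluate_segments(
    scores: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, ClassificationMetrics]:
    """Overall metrics at the overall Youden cutoff, optionally split by a
    per-segment group key (e.g. participant OSA severity).

    The group rows use the *overall* cutoff, so their confusion counts
    partition the overall ones exactly; per-group AUROCs are computed on
    the group's own scores.
    """
    cutoff, overall = youden_cutoff(scores, labels)
    out = {"Overall": overall}
    if groups is not None:
        groups = np.asarray(groups)
        for g in dict.fromkeys(groups):  # preserve appearance order
            sel = groups == g
            tp, fn, tn, fp = confusion_counts(scores[sel], labels[sel], cutoff)
            try:
                auc, ci = roc_auroc(scores[sel], np.asarray(labels)[sel])
            except EvaluationError:
                auc, ci = None, None
            out[str(g)] = ClassificationMetrics.from_counts(
                tp, fn, tn, fp, cutoff=cutoff, auroc=auc, auroc_ci=ci
            )
    return out
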