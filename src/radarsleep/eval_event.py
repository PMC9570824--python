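"""Full-night event detection evaluation.

Segment predictions are merged into one per-second abnormal-probability
track per recording (seconds covered by two overlapping 60-s segments get
the mean of the two), events are extracted as maximal above-threshold runs
of at least 10 s, and predicted events are matched one-to-one to reference
events at an IoU threshold of 0.5 (greedy, in descending IoU order).  The
operating threshold is chosen on a 0.01 grid to maximize the cohort-pooled
F1.  Because the radar records wake as well as sleep, detections can also
be filtered to *in-sleep* events — those with strictly more than half of
their seconds spent asleep — before counting false positives or estimating
the AHI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import EventInterval
from .preprocessing import SEGMENT_S, STRIDE_S

MIN_EVENT_S = 10
IOU_MIN = 0.5
THRESHOLD_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


class EventEvalError(ValueError):
    pass


@dataclass
class NightTrack:
    """Whole-recording per-second abnormal probabilities plus sleep mask."""

    abnormal_prob: np.ndarray
    sleep_mask: np.ndarray

    def __post_init__(self) -> None:
        self.abnormal_prob = np.asarray(self.abnormal_prob, dtype=float)
        self.sleep_mask = np.asarray(self.sleep_mask, dtype=bool)
        if self.abnormal_prob.shape != self.sleep_mask.shape:
            raise EventEvalError("probability track and sleep mask differ in length")
        if np.any((self.abnormal_prob < 0) | (self.abnormal_prob > 1)):
            raise EventEvalError("probabilities outside [0, 1]")


def merge_segments(
    frame_tracks: Sequence[np.ndarray], starts_s: Sequence[float]
) -> np.ndarray:
    """Average overlapping 60-frame segment tracks into one 1-Hz track.

    Segments must sit on the 0/30/60... grid; each second's value is the
    mean of the one or two segment predictions covering it.
    """
    starts = np.asarray(starts_s, dtype=float)
    if starts.size == 0:
        return np.zeros(0)
    if np.any(np.mod(starts, STRIDE_S) != 0):
        raise EventEvalError("segment starts must lie on the 30-s grid")
    n_seconds = int(starts.max()) + SEGMENT_S
    total = np.zeros(n_seconds)
    count = np.zeros(n_seconds)
    for track, start in zip(frame_tracks, starts):
        track = np.asarray(track, dtype=float)
        if track.size != SEGMENT_S:
            raise EventEvalError(f"expected 60-frame tracks, got {track.size}")
        s = int(start)
        total[s : s + SEGMENT_S] += track
        count[s : s + SEGMENT_S] += 1
    if np.any(count == 0):
        raise EventEvalError("gap in segment coverage: starts are not contiguous")
    return total / count


def extract_events(track: np.ndarray, threshold: float) -> list[EventInterval]:
    """Maximal runs with probability >= threshold lasting >= 10 s."""
    if not 0.0 <= threshold <= 1.0:
        raise EventEvalError(f"threshold {threshold} outside [0, 1]")
    track = np.asarray(track, dtype=float)
    above = np.concatenate([[False], track >= threshold, [False]])
    edges = np.flatnonzero(np.diff(above.astype(int)))
    events = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= MIN_EVENT_S:
            events.append(EventInterval(float(start), float(end)))
    return events


@dataclass
class MatchResult:
    """One-to-one IoU matching outcome over a recording or pooled cohort."""

    matched: list[tuple[EventInterval, EventInterval]] = field(default_factory=list)
    false_positives: list[EventInterval] = field(default_factory=list)
    false_negatives: list[EventInterval] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.matched)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)

    @property
    def sensitivity(self) -> float:
        den = self.tp + self.fn
        return self.tp / den if den else float("nan")

    @property
    def ppv(self) -> float:
        den = self.tp + self.fp
        return self.tp / den if den else float("nan")

    @property
    def f1(self) -> float:
        den = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / den if den else 0.0

    def per_class_sensitivity(self) -> dict[str, tuple[float, int, int]]:
        """Sensitivity per truth class: label -> (value, matched, total)."""
        totals: dict[str, int] = {}
        hits: dict[str, int] = {}
        for _, truth in self.matched:
            if truth.label:
                hits[truth.label] = hits.get(truth.label, 0) + 1
                totals[truth.label] = totals.get(truth.label, 0) + 1
        for truth in self.false_negatives:
            if truth.label:
                totals[truth.label] = totals.get(truth.label, 0) + 1
        return {
            lab: (hits.get(lab, 0) / tot if tot else float("nan"), hits.get(lab, 0), tot)
            for lab, tot in totals.items()
        }

    def merge(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.matched + other.matched,
            self.false_positives + other.false_positives,
            self.false_negatives + other.false_negatives,
        )


def _check_disjoint(events: Sequence[EventInterval], name: str) -> None:
    ordered = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise EventEvalError(
                f"{name} intervals overlap: [{a.start_s}, {a.end_s}) and "
                f"[{b.start_s}, {b.end_s})"
            )


def iou_match(
    predicted: Sequence[EventInterval],
    truth: Sequence[EventInterval],
    iou_min: float = IOU_MIN,
) -> MatchResult:
    """Greedy one-to-one matching in descending IoU order.

    Pairs with IoU >= ``iou_min`` become true positives; leftover
    predictions are false positives and leftover truths false negatives.
    Both lists must be internally disjoint.
    """
    _check_disjoint(predicted, "predicted")
    _check_disjoint(truth, "truth")
    pairs = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            iou = p.iou(t)
            if iou >= iou_min:
                pairs.append((iou, i, j))
    # descending IoU; ties broken by list order for determinism
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    result = MatchResult()
    for iou, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        result.matched.append((predicted[i], truth[j]))
    result.false_positives = [p for i, p in enumerate(predicted) if i not in used_p]
    result.false_negatives = [t for j, t in enumerate(truth) if j not in used_t]
    return result


def in_sleep_filter(
    events: Sequence[EventInterval], sleep_mask: np.ndarray
) -> list[EventInterval]:
    """Keep events whose seconds are strictly more than half asleep."""
    mask = np.asarray(sleep_mask, dtype=bool)
    kept = []
    for ev in events:
        lo = int(ev.start_s)
        hi = int(np.ceil(ev.end_s))
        seconds = mask[lo : min(hi, mask.size)]
        n_total = hi - lo
        if seconds.sum() * 2 > n_total:
            kept.append(ev)
    return kept


def f1_threshold(
    tracks: Sequence[np.ndarray],
    truths: Sequence[Sequence[EventInterval]],
    iou_min: float = IOU_MIN,
    grid: np.ndarray = THRESHOLD_GRID,
) -> tuple[float, MatchResult]:
    """Operating threshold maximizing cohort-pooled F1 on a 0.01 grid.

    Ties resolve to the lower threshold.  Raises when the cohort has no
    reference events (F1 would be degenerate everywhere).
    """
    if sum(len(t) for t in truths) == 0:
        raise EventEvalError("no truth events in cohort")
    best_f1, best_thr, best_res = -1.0, None, None
    for thr in grid:
        pooled = MatchResult()
        for track, truth in zip(tracks, truths):
            pooled = pooled.merge(iou_match(extract_events(track, thr), truth, iou_min))
        if pooled.f1 > best_f1:
            best_f1, best_thr, best_res = pooled.f1, float(thr), pooled
    return best_thr, best_res


@dataclass
class CohortDetection:
    """Per-recording detection outcome at one threshold."""

    recording_ids: list[str]
    events: dict[str, list[EventInterval]]          # all detections
    events_in_sleep: dict[str, list[EventInterval]]  # after the sleep filter
    match: MatchResult                               # pooled, all detections
    threshold: float

    @property
    def fp_per_participant(self) -> float:
        return self.match.fp / len(self.recording_ids)


def detect_cohort(
    tracks: dict[str, NightTrack],
    truths: dict[str, Sequence[EventInterval]],
    threshold: float | None = None,
    iou_min: float = IOU_MIN,
) -> CohortDetection:
    """Extract + match events for every recording at one threshold.

    When ``threshold`` is None it is first optimized by pooled F1.
    """
    ids = list(tracks)
    if threshold is None:
        threshold, _ = f1_threshold(
            [tracks[i].abnormal_prob for i in ids], [truths[i] for i in ids], iou_min
        )
    events: dict[str, list[EventInterval]] = {}
    events_sleep: dict[str, list[EventInterval]] = {}
    pooled = MatchResult()
    for rid in ids:
        evs = extract_events(tracks[rid].abnormal_prob, threshold)
        events[rid] = evs
        events_sleep[rid] = in_sleep_filter(evs, tracks[rid].sleep_mask)
        pooled = pooled.merge(iou_match(evs, truths[rid], iou_min))
    return CohortDetection(ids, events, events_sleep, pooled, threshold)


def fp_per_participant(
    detection: CohortDetection,
    truths: dict[str, Sequence[EventInterval]],
    in_sleep: bool = False,
    iou_min: float = IOU_MIN,
) -> float:
    """Mean false-positive detections per participant.

    With ``in_sleep=True`` only detections surviving the sleep filter are
    counted (matching is re-run on the filtered lists).
    """
    events = detection.events_in_sleep if in_sleep else detection.events
    total_fp = 0
    for rid in detection.recording_ids:
        total_fp += iou_match(events[rid], truths[rid], iou_min).fp
    return total_fp / len(detection.recording_ids)
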