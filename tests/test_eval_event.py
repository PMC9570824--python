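"""Track merging, event extraction, IoU matching, F1 threshold, sleep filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarsleep.eval_event import (
    EventEvalError,
    NightTrack,
    detect_cohort,
    extract_events,
    f1_threshold,
    fp_per_participant,
    in_sleep_filter,
    iou_match,
    merge_segments,
)
from radarsleep.io_formats import EventInterval


def _iv(start, end, label=None):
    return EventInterval(float(start), float(end), label=label)


class TestMergeSegments:
    def test_overlap_averages_edge_passes_through(self, rng):
        t0 = rng.random(60)
        t1 = rng.random(60)
        merged = merge_segments([t0, t1], [0.0, 30.0])
        assert merged.size == 90
        # seconds 0-29 covered only by the first segment
        assert np.allclose(merged[:30], t0[:30])
        # seconds 30-59 covered by both: frame 45 is t0[45] and t1[15]
        assert merged[45] == pytest.approx((t0[45] + t1[15]) / 2)
        # tail covered only by the second
        assert np.allclose(merged[60:], t1[30:])

    def test_matches_per_second_enumeration(self, rng):
        tracks = [rng.random(60) for _ in range(5)]
        starts = [0.0, 30.0, 60.0, 90.0, 120.0]
        merged = merge_segments(tracks, starts)
        for sec in range(merged.size):
            cover = [
                tr[sec - int(s)]
                for tr, s in zip(tracks, starts)
                if s <= sec < s + 60
            ]
            assert merged[sec] == pytest.approx(np.mean(cover))

    def test_off_grid_start_rejected(self, rng):
        with pytest.raises(EventEvalError, match="grid"):
            merge_segments([rng.random(60)], [15.0])


class TestExtractEvents:
    def test_long_run_extracted(self):
        track = np.zeros(100)
        track[20:32] = 0.9
        events = extract_events(track, 0.5)
        assert events == [_iv(20, 32)]

    def test_nine_second_run_dropped(self):
        track = np.zeros(100)
        track[20:29] = 0.9
        assert extract_events(track, 0.5) == []

    def test_single_dip_splits_runs(self):
        track = np.zeros(100)
        track[10:25] = 0.9
        track[25] = 0.1
        track[26:40] = 0.9
        assert extract_events(track, 0.5) == [_iv(10, 25), _iv(26, 40)]

    def test_threshold_is_inclusive(self):
        track = np.zeros(50)
        track[0:12] = 0.5
        assert extract_events(track, 0.5) == [_iv(0, 12)]

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_nesting_across_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        track = np.round(rng.random(200), 2)
        lo = extract_events(track, 0.3)
        hi = extract_events(track, 0.7)
        for ev in hi:
            assert any(
                c.start_s <= ev.start_s and ev.end_s <= c.end_s for c in lo
            )


class TestIouMatch:
    def test_identical_lists_all_match(self):
        truth = [_iv(0, 20, "H"), _iv(50, 70, "OA")]
        pred = [_iv(0, 20), _iv(50, 70)]
        res = iou_match(pred, truth)
        assert res.tp == 2 and res.fp == 0 and res.fn == 0

    def test_low_iou_counts_fp_and_fn(self):
        res = iou_match([_iv(0, 10)], [_iv(5, 15, "H")])  # IoU 5/15
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    def test_iou_three_quarters_matches(self):
        res = iou_match([_iv(5, 20)], [_iv(0, 20, "CA")])  # IoU 15/20
        assert res.tp == 1
        assert res.per_class_sensitivity()["CA"][0] == 1.0

    def test_matching_is_one_to_one(self):
        # both halves of the truth reach IoU exactly 0.5; only one may match
        truth = [_iv(0, 20, "H")]
        pred = [_iv(0, 10), _iv(10, 20)]
        res = iou_match(pred, truth)
        assert res.tp == 1 and res.fp == 1 and res.fn == 0
        assert res.matched[0][0] == _iv(0, 10)  # deterministic tie-break

    def test_greedy_prefers_higher_iou_across_pairs(self):
        # pred A overlaps both truths; greedy must give it to the closer
        # truth and leave the other to pred B
        truth = [_iv(0, 20, "H"), _iv(22, 40, "OA")]
        pred = [_iv(2, 22), _iv(24, 40)]
        res = iou_match(pred, truth)
        assert res.tp == 2
        pairs = {(p.start_s, t.start_s) for p, t in res.matched}
        assert pairs == {(2.0, 0.0), (24.0, 22.0)}

    def test_overlapping_intervals_within_list_rejected(self):
        with pytest.raises(EventEvalError, match="overlap"):
            iou_match([_iv(0, 10), _iv(5, 15)], [])

    def test_tp_count_symmetric(self, rng):
        for _ in range(20):
            pred, truth = _random_interval_lists(rng)
            forward = iou_match(pred, truth)
            backward = iou_match(truth, pred)
            assert forward.tp == backward.tp


def _random_interval_lists(rng, span=300):
    def build(labels):
        out, cursor = [], 0.0
        while True:
            start = cursor + rng.uniform(0, 40)
            end = start + rng.uniform(10, 40)
            if end >= span:
                return out
            out.append(_iv(round(start), round(end),
                           "H" if labels and rng.random() < 0.7 else
                           ("OA" if labels else None)))
            cursor = end

    return build(labels=False), build(labels=True)


class TestInSleepFilter:
    def test_wake_event_removed_sleep_event_kept(self):
        mask = np.zeros(100, dtype=bool)
        mask[50:] = True
        events = [_iv(0, 20), _iv(60, 80)]
        assert in_sleep_filter(events, mask) == [_iv(60, 80)]

    def test_majority_asleep_kept(self):
        mask = np.zeros(40, dtype=bool)
        mask[0:12] = True  # 12 of 20 s asleep
        assert in_sleep_filter([_iv(0, 20)], mask) == [_iv(0, 20)]

    def test_exactly_half_asleep_removed(self):
        mask = np.zeros(40, dtype=bool)
        mask[0:10] = True  # exactly half
        assert in_sleep_filter([_iv(0, 20)], mask) == []


class TestF1Threshold:
    def test_perfect_candidate_reaches_f1_one(self):
        track = np.zeros(200)
        track[30:50] = 0.8
        track[100:115] = 0.8
        truth = [_iv(30, 50, "H"), _iv(100, 115, "OA")]
        thr, res = f1_threshold([track], [truth])
        assert res.f1 == 1.0
        assert thr <= 0.8

    def test_matches_exhaustive_grid_oracle(self, rng):
        tracks, truths = [], []
        for _ in range(3):
            track = np.round(rng.random(240), 2)
            track[40:55] += 0.5
            track[120:140] += 0.6
            tracks.append(np.clip(track, 0, 1))
            truths.append([_iv(40, 55, "H"), _iv(121, 140, "OA")])
        thr, res = f1_threshold(tracks, truths)
        best = (-1.0, None)
        for cand in np.round(np.arange(0, 1.001, 0.01), 2):
            tp = fp = fn = 0
            for track, truth in zip(tracks, truths):
                m = iou_match(extract_events(track, cand), truth)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best[0]:
                best = (f1, cand)
        assert thr == best[1]
        assert res.f1 == pytest.approx(best[0])

    def test_no_truth_events_rejected(self):
        with pytest.raises(EventEvalError, match="no truth"):
            f1_threshold([np.zeros(100)], [[]])


class TestCohortDetection:
    def _cohort(self, rng):
        tracks, truths = {}, {}
        for k in range(3):
            prob = np.clip(rng.normal(0.15, 0.1, 600), 0, 1)
            truth = [_iv(100 + 150 * k, 125 + 150 * k, "H")]
            for ev in truth:
                prob[int(ev.start_s) : int(ev.end_s)] = rng.uniform(0.7, 0.95)
            # a spurious wake-time detection
            prob[400:415] = 0.9
            sleep = np.ones(600, dtype=bool)
            sleep[380:430] = False
            tracks[f"r{k}"] = NightTrack(prob, sleep)
            truths[f"r{k}"] = truth
        return tracks, truths

    def test_in_sleep_fp_never_exceeds_overall(self, rng):
        tracks, truths = self._cohort(rng)
        det = detect_cohort(tracks, truths)
        fp_all = fp_per_participant(det, truths, in_sleep=False)
        fp_sleep = fp_per_participant(det, truths, in_sleep=True)
        assert fp_sleep <= fp_all
        assert fp_all > 0  # the injected wake detections are false positives

    def test_threshold_optimized_when_not_given(self, rng):
        tracks, truths = self._cohort(rng)
        det = detect_cohort(tracks, truths)
        assert det.match.sensitivity == 1.0
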