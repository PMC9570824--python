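"""Segment preparation: resample to 8 Hz, window, normalize, rasterize labels.

The detector consumes 60-s windows of the respiratory trace taken every
30 s (so consecutive windows share 30 s of signal), resampled to 8 Hz
(480 samples) and z-scored per window.  Reference events are rasterized to
a 1-s class track per window, and a window is *abnormal* when at least 10
consecutive seconds are labeled with any apnea/hypopnea class — the same
10-s floor the scoring rules use for events themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import EventInterval, RespRecording

TARGET_RATE_HZ = 8.0
SEGMENT_S = 60
STRIDE_S = 30
SAMPLES_PER_SEGMENT = int(SEGMENT_S * TARGET_RATE_HZ)  # 480

#: Frame-label codes at 1 Hz.
CLASS_CODES = {"Normal": 0, "H": 1, "OA": 2, "CA": 3}
CODE_LABELS = {v: k for k, v in CLASS_CODES.items()}
#: Overlap priority when two events cover the same second.
LABEL_PRIORITY = ("OA", "CA", "H")

MIN_ABNORMAL_RUN_S = 10


class PreprocessingError(ValueError):
    pass


def resample_fourier(
    trace: Sequence[float], rate_in: float, rate_out: float = TARGET_RATE_HZ
) -> np.ndarray:
    """Fourier-domain resampling of the trace to ``rate_out``.

    Output length is ``round(duration_s * rate_out)``; content below the
    output Nyquist (4 Hz at the 8 Hz default) is preserved.
    """
    if not rate_in > rate_out > 0:
        raise PreprocessingError(
            f"need rate_in > rate_out > 0, got {rate_in} -> {rate_out}"
        )
    trace = np.asarray(trace, dtype=float)
    n_out = int(round(trace.size / rate_in * rate_out))
    return sps.resample(trace, n_out)


def segment(trace_8hz: Sequence[float]) -> list[tuple[float, np.ndarray]]:
    """Cut 60-s windows every 30 s; an incomplete tail window is dropped."""
    trace = np.asarray(trace_8hz, dtype=float)
    out = []
    step = int(STRIDE_S * TARGET_RATE_HZ)
    start = 0
    while start + SAMPLES_PER_SEGMENT <= trace.size:
        out.append((start / TARGET_RATE_HZ, trace[start : start + SAMPLES_PER_SEGMENT]))
        start += step
    return out


def znorm(window: Sequence[float]) -> np.ndarray:
    """Z-score one window; a flat window maps to all zeros."""
    w = np.asarray(window, dtype=float)
    sd = w.std()
    if sd == 0:
        return np.zeros_like(w)
    return (w - w.mean()) / sd


def rasterize_labels(
    events: Sequence[EventInterval], start_s: float, duration_s: float = SEGMENT_S
) -> np.ndarray:
    """1-Hz class track for the window starting at ``start_s``.

    Second ``t`` takes the class of the event covering its midpoint
    ``start_s + t + 0.5``; overlaps resolve by priority OA > CA > H, and
    uncovered seconds are Normal.
    """
    n = int(round(duration_s))
    track = np.zeros(n, dtype=np.int64)
    mids = start_s + np.arange(n) + 0.5
    for label in reversed(LABEL_PRIORITY):  # lowest priority first, higher overwrite
        code = CLASS_CODES[label]
        for ev in events:
            if ev.label != label:
                continue
            covered = (mids >= ev.start_s) & (mids < ev.end_s)
            track[covered] = code
    return track


def segment_class(frame_labels: Sequence[int]) -> int:
    """Window class from its 1-Hz track.

    Abnormal iff some run of >= 10 consecutive non-Normal seconds exists;
    the multiclass label is the class of the longest qualifying run
    (dominant class within the run by count, run ties broken by the earlier
    run).  Returns a CLASS_CODES value, 0 for Normal.
    """
    track = np.asarray(frame_labels, dtype=np.int64)
    best_len = 0
    best_code = 0
    i = 0
    n = track.size
    while i < n:
        if track[i] == 0:
            i += 1
            continue
        j = i
        while j < n and track[j] != 0:
            j += 1
        run_len = j - i
        if run_len >= MIN_ABNORMAL_RUN_S and run_len > best_len:
            best_len = run_len
            counts = np.bincount(track[i:j], minlength=4)
            best_code = int(np.argmax(counts[1:]) + 1)
        i = j
    return best_code


@dataclass
class SegmentSet:
    """Windows and labels for one recording (or a concatenated cohort).

    segments : (n, 480) z-scored windows
    starts_s : window start times on the 0/30/60... grid
    frame_labels : (n, 60) class codes at 1 Hz
    segment_class : (n,) multiclass window codes (0 = Normal)
    recording_ids : participant id per window
    """

    segments: np.ndarray
    starts_s: np.ndarray
    frame_labels: np.ndarray
    segment_class: np.ndarray
    recording_ids: np.ndarray

    def __post_init__(self) -> None:
        n = self.segments.shape[0]
        if self.segments.shape != (n, SAMPLES_PER_SEGMENT):
            raise PreprocessingError(
                f"segments must be (n, {SAMPLES_PER_SEGMENT}), got {self.segments.shape}"
            )
        if self.frame_labels.shape != (n, SEGMENT_S):
            raise PreprocessingError("frame_labels must be (n, 60)")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def binary_class(self) -> np.ndarray:
        return (self.segment_class > 0).astype(np.int64)

    @property
    def binary_frame_labels(self) -> np.ndarray:
        return (self.frame_labels > 0).astype(np.int64)

    def save(self, arrays_path: str | Path, index_path: str | Path) -> None:
        """Binary array container plus a CSV index (id, start_s, class)."""
        np.savez_compressed(
            arrays_path,
            segments=self.segments,
            starts_s=self.starts_s,
            frame_labels=self.frame_labels,
            segment_class=self.segment_class,
            recording_ids=self.recording_ids.astype(str),
        )
        pd.DataFrame(
            {
                "recording_id": self.recording_ids,
                "start_s": self.starts_s,
                "segment_class": self.segment_class,
            }
        ).to_csv(index_path, index=False)

    @classmethod
    def load(cls, arrays_path: str | Path) -> "SegmentSet":
        with np.load(arrays_path, allow_pickle=False) as d:
            return cls(
                segments=d["segments"],
                starts_s=d["starts_s"],
                frame_labels=d["frame_labels"],
                segment_class=d["segment_class"],
                recording_ids=d["recording_ids"],
            )

    @classmethod
    def concatenate(cls, sets: Sequence["SegmentSet"]) -> "SegmentSet":
        return cls(
            segments=np.concatenate([s.segments for s in sets]),
            starts_s=np.concatenate([s.starts_s for s in sets]),
            frame_labels=np.concatenate([s.frame_labels for s in sets]),
            segment_class=np.concatenate([s.segment_class for s in sets]),
            recording_ids=np.concatenate([s.recording_ids for s in sets]),
        )

    def subset(self, mask: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            self.segments[mask],
            self.starts_s[mask],
            self.frame_labels[mask],
            self.segment_class[mask],
            self.recording_ids[mask],
        )


def prepare_recording(rec: RespRecording) -> SegmentSet:
    """Resample, window, z-score and label one recording."""
    trace8 = resample_fourier(rec.trace, rec.rate_hz, TARGET_RATE_HZ)
    windows = segment(trace8)
    n = len(windows)
    segments = np.zeros((n, SAMPLES_PER_SEGMENT))
    starts = np.zeros(n)
    frames = np.zeros((n, SEGMENT_S), dtype=np.int64)
    classes = np.zeros(n, dtype=np.int64)
    for k, (start_s, w) in enumerate(windows):
        segments[k] = znorm(w)
        starts[k] = start_s
        frames[k] = rasterize_labels(rec.events, start_s)
        classes[k] = segment_class(frames[k])
    ids = np.full(n, rec.id, dtype=object)
    return SegmentSet(segments, starts, frames, classes, ids.astype(str))
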