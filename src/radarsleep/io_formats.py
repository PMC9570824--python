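"""Containers and file formats for radar sleep recordings.

A recording is a respiratory-effort trace plus two pieces of reference
scoring from polysomnography: an event table (hypopnea ``H``, obstructive
apnea ``OA``, central apnea ``CA``; onset and offset in seconds) and a
hypnogram of 30-s sleep-stage epochs (``W``, ``N1``, ``N2``, ``N3``,
``REM``).  All times are seconds from recording start and all intervals are
half-open ``[start, end)``.

Canonical interchange formats are plain CSV:

* signal:     columns ``time_s, value`` (monotone time)
* annotation: columns ``start_s, end_s, label``
* hypnogram:  columns ``epoch_index, stage``

EDF signal files are accepted as well when ``mne`` is importable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("radarsleep")

#: Native sampling rate of the radar respiratory trace, Hz.
NATIVE_RATE_HZ = 1000.0 / 33.0

EVENT_LABELS = ("H", "OA", "CA")
STAGES = ("W", "N1", "N2", "N3", "REM")
EPOCH_S = 30.0
#: Minimum duration of a scoreable apnea/hypopnea event, seconds.
MIN_EVENT_S = 10.0


class FormatError(ValueError):
    """A file failed validation; the message names the offending row."""


@dataclass(frozen=True)
class EventInterval:
    """A labeled (ground truth) or scored (predicted) time interval.

    Ground-truth events carry ``label`` in {H, OA, CA} and must last at
    least 10 s; predicted events carry a detection ``score`` in [0, 1].
    """

    start_s: float
    end_s: float
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise FormatError(
                f"event interval [{self.start_s}, {self.end_s}) has start >= end"
            )
        if self.label is not None:
            if self.label not in EVENT_LABELS:
                raise FormatError(f"unknown event label {self.label!r}")
            if self.duration_s < MIN_EVENT_S:
                raise FormatError(
                    f"ground-truth event [{self.start_s}, {self.end_s}) shorter "
                    f"than {MIN_EVENT_S:g} s"
                )
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise FormatError(f"event score {self.score} outside [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def iou(self, other: "EventInterval") -> float:
        """Intersection over union of two half-open intervals."""
        inter = min(self.end_s, other.end_s) - max(self.start_s, other.start_s)
        if inter <= 0:
            return 0.0
        union = self.duration_s + other.duration_s - inter
        return inter / union


@dataclass(frozen=True)
class Hypnogram:
    """Sleep stages at 30-s epochs."""

    epochs: tuple[str, ...]

    def __post_init__(self) -> None:
        for i, st in enumerate(self.epochs):
            if st not in STAGES:
                raise FormatError(f"hypnogram epoch {i}: unknown stage {st!r}")

    @property
    def duration_s(self) -> float:
        return EPOCH_S * len(self.epochs)

    @property
    def total_sleep_time_s(self) -> float:
        """Total sleep time: 30 s per non-wake epoch."""
        return EPOCH_S * sum(1 for st in self.epochs if st != "W")

    def sleep_mask_1hz(self, n_seconds: int | None = None) -> np.ndarray:
        """Boolean per-second mask, True while asleep.

        Epochs are expanded by repetition (30 seconds each); seconds past
        the last epoch are treated as wake.
        """
        mask = np.repeat([st != "W" for st in self.epochs], int(EPOCH_S))
        if n_seconds is not None:
            if n_seconds <= mask.size:
                mask = mask[:n_seconds]
            else:
                mask = np.concatenate(
                    [mask, np.zeros(n_seconds - mask.size, dtype=bool)]
                )
        return mask.astype(bool)


@dataclass
class RespRecording:
    """One participant's respiratory-effort trace with reference scoring."""

    id: str
    trace: np.ndarray
    rate_hz: float = NATIVE_RATE_HZ
    events: list[EventInterval] = field(default_factory=list)
    hypnogram: Hypnogram = field(default_factory=lambda: Hypnogram(()))

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.rate_hz <= 0:
            raise FormatError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.trace.size == 0:
            raise FormatError("empty signal")
        clipped = []
        for ev in self.events:
            if ev.start_s >= self.duration_s:
                logger.warning(
                    "recording %s: dropping event [%g, %g) beyond duration %g s",
                    self.id, ev.start_s, ev.end_s, self.duration_s,
                )
                continue
            if ev.end_s > self.duration_s:
                logger.warning(
                    "recording %s: clipping event [%g, %g) to duration %g s",
                    self.id, ev.start_s, ev.end_s, self.duration_s,
                )
                if ev.label is not None and self.duration_s - ev.start_s < MIN_EVENT_S:
                    # clipping would leave a sub-scoreable stub
                    continue
                ev = dataclasses.replace(ev, end_s=self.duration_s)
            clipped.append(ev)
        self.events = clipped

    @property
    def duration_s(self) -> float:
        return self.trace.size / self.rate_hz


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_signal(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a respiratory trace; returns ``(values, rate_hz)``.

    CSV files need ``time_s, value`` columns with a strictly increasing,
    uniformly spaced time column; ``.edf`` files are read through mne
    (first channel).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data()[0].astype(float), float(raw.info["sfreq"])
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "value"], path)
    if len(df) == 0:
        raise FormatError(f"{path}: empty signal")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size > 1:
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise FormatError(
                f"{path}: non-monotone time column at row {int(bad[0]) + 1}"
            )
        rate = 1.0 / float(np.median(dt))
    else:
        rate = NATIVE_RATE_HZ
    return df["value"].to_numpy(dtype=float), rate


def read_annotations(
    path: str | Path, unknown_labels: str = "error"
) -> list[EventInterval]:
    """Read a ``start_s, end_s, label`` event table.

    ``unknown_labels`` controls rows whose label is not in {H, OA, CA}:
    ``"error"`` raises, ``"oa"`` maps them to OA, ``"drop"`` discards them.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["start_s", "end_s", "label"], path)
    events: list[EventInterval] = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = str(row.label)
        if label not in EVENT_LABELS:
            if unknown_labels == "drop":
                logger.warning("%s: row %d: dropping unknown label %r", path, i, label)
                continue
            if unknown_labels == "oa":
                label = "OA"
            else:
                raise FormatError(f"{path}: row {i}: unknown label {row.label!r}")
        try:
            events.append(
                EventInterval(float(row.start_s), float(row.end_s), label=label)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return events


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read an ``epoch_index, stage`` hypnogram table (30-s epochs)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["epoch_index", "stage"], path)
    df = df.sort_values("epoch_index")
    idx = df["epoch_index"].to_numpy(dtype=int)
    if idx.size and not np.array_equal(idx, np.arange(idx.size)):
        raise FormatError(f"{path}: epoch_index must run 0..{idx.size - 1} contiguously")
    try:
        return Hypnogram(tuple(str(s) for s in df["stage"]))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_recording(
    signal_path: str | Path,
    annotation_path: str | Path,
    hypnogram_path: str | Path,
    recording_id: str | None = None,
    unknown_labels: str = "error",
) -> RespRecording:
    """Load and validate one participant's signal, events and hypnogram."""
    trace, rate = read_signal(signal_path)
    events = read_annotations(annotation_path, unknown_labels=unknown_labels)
    hyp = read_hypnogram(hypnogram_path)
    rid = recording_id if recording_id is not None else Path(signal_path).stem
    return RespRecording(id=rid, trace=trace, rate_hz=rate, events=events, hypnogram=hyp)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_signal(trace: Sequence[float], rate_hz: float, path: str | Path) -> None:
    trace = np.asarray(trace, dtype=float)
    t = np.arange(trace.size) / rate_hz
    pd.DataFrame({"time_s": t, "value": trace}).to_csv(path, index=False)


def write_annotations(events: Sequence[EventInterval], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "label": [e.label for e in events],
        }
    ).to_csv(path, index=False)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp.epochs)), "stage": list(hyp.epochs)}
    ).to_csv(path, index=False)


def write_recording(rec: RespRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write the CSV triplet for one recording; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "signal": out_dir / f"{rec.id}_signal.csv",
        "annotations": out_dir / f"{rec.id}_events.csv",
        "hypnogram": out_dir / f"{rec.id}_hypnogram.csv",
    }
    write_signal(rec.trace, rec.rate_hz, paths["signal"])
    write_annotations(rec.events, paths["annotations"])
    write_hypnogram(rec.hypnogram, paths["hypnogram"])
    return paths


# ---------------------------------------------------------------------------
# raw IQ (one range bin) as two real columns
# ---------------------------------------------------------------------------

def write_iq(samples: Sequence[complex], path: str | Path) -> None:
    z = np.asarray(samples, dtype=complex)
    pd.DataFrame(
        {"chirp_index": np.arange(z.size), "i": z.real, "q": z.imag}
    ).to_csv(path, index=False)


def read_iq(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["chirp_index", "i", "q"], path)
    return df["i"].to_numpy(dtype=float) + 1j * df["q"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# agreement report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Cohort-level AHI agreement between estimate and reference scoring.

    Per-participant AHI pairs plus the agreement statistics: Pearson r,
    ICC(2,1), Bland-Altman bias with its CI and 95% limits of agreement,
    linear weighted kappa on the four severity classes, and the severity
    confusion matrix (rows = reference, columns = estimate).
    """

    participants: list[str]
    ahi_true: list[float]
    ahi_est: list[float]
    ahi_est_corrected: list[float]
    severity_true: list[str]
    severity_est: list[str]
    severity_est_corrected: list[str]
    pearson_r: float
    icc: float
    bland_altman: dict  # bias, bias_ci (2-list), loa_low, loa_high
    kappa_linear: float
    confusion: list[list[int]]  # 4x4, rows true, cols estimated

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(**d)


def write_report(report: AgreementReport, path: str | Path) -> None:
    """Write a JSON report plus a human-readable ``.txt`` summary next to it."""
    if not report.participants:
        raise FormatError("no participants")
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2, default=float) + "\n")
    lines = [
        "AHI agreement report",
        f"participants: {len(report.participants)}",
        f"Pearson r        : {report.pearson_r:.3f}",
        f"ICC(2,1)         : {report.icc:.3f}",
        "Bland-Altman bias: {bias:.2f} [{lo:.2f}, {hi:.2f}], LOA [{l:.1f}, {u:.1f}]".format(
            bias=report.bland_altman["bias"],
            lo=report.bland_altman["bias_ci"][0],
            hi=report.bland_altman["bias_ci"][1],
            l=report.bland_altman["loa_low"],
            u=report.bland_altman["loa_high"],
        ),
        f"linear kappa     : {report.kappa_linear:.3f}",
        "",
        "participant  ahi_true  ahi_est  ahi_corr  sev_true  sev_est",
    ]
    for i, pid in enumerate(report.participants):
        lines.append(
            f"{pid:<12} {report.ahi_true[i]:8.1f} {report.ahi_est[i]:8.1f} "
            f"{report.ahi_est_corrected[i]:9.1f}  {report.severity_true[i]:<8} "
            f"{report.severity_est[i]}"
        )
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> AgreementReport:
    return AgreementReport.from_dict(json.loads(Path(path).read_text()))


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
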