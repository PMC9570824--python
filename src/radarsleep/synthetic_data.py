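"""Synthetic cohort generator: breathing traces, events, hypnograms, radar IQ.

No public radar/PSG cohort accompanies this problem, so every pipeline
stage is exercised on simulated recordings that carry the statistical
structure the detector assumes:

* quasi-periodic breathing effort in the 0.2-0.3 Hz band with slow
  amplitude and rate drift;
* hypopneas as a 30-70% amplitude reduction of the local baseline,
  central apneas as near-absent effort (<= 5%), obstructive apneas as
  persistent but reduced (20-50%) and distorted effort — amplitude
  semantics on the *effort* signal, which is what a radar pointed at the
  chest actually sees;
* events last 10-60 s, never overlap, keep a >= 10 s gap, and lie inside
  sleep;
* wake epochs carry irregular, high-variance body-motion signal;
* a 30-s epoch hypnogram with a sleep-latency block and brief awakenings.

The radar IQ model places the trajectory on a circle of the complex
plane: ``z_k = A exp(i 4 pi d_k / lambda) + offset + noise`` with a 60 GHz
carrier (lambda = 5 mm), which is what vector-difference demodulation
inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    EPOCH_S,
    NATIVE_RATE_HZ,
    EventInterval,
    Hypnogram,
    RespRecording,
)
from .radar_demod import IQSeries

WAVELENGTH_M = 0.005  # 60 GHz carrier


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    The apnea-hypopnea index (AHI) target is drawn uniformly per
    participant, the class mix follows the cohort event composition
    (hypopnea-dominant, central apnea rare), and event durations are
    uniform over the scoreable 10-60 s range.
    """

    n_participants: int = 20
    duration_s: float = 7200.0
    ahi_range: tuple[float, float] = (0.0, 60.0)
    class_mix: tuple[float, float, float] = (0.710, 0.266, 0.024)  # H, OA, CA
    event_duration_s: tuple[float, float] = (10.0, 60.0)
    breathing_band_hz: tuple[float, float] = (0.2, 0.3)
    noise_sd: float = 0.1
    sleep_efficiency_range: tuple[float, float] = (0.65, 0.95)
    rate_hz: float = NATIVE_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-6:
            raise SimulationError("class_mix fractions must sum to 1")
        if self.event_duration_s[0] < 10.0:
            raise SimulationError("event durations must be >= 10 s")


_CLASSES = ("H", "OA", "CA")


def _make_hypnogram(
    n_epochs: int, sleep_efficiency: float, rng: np.random.Generator
) -> Hypnogram:
    """Sleep-latency wake block, then cycling sleep with brief awakenings."""
    n_wake = int(round(n_epochs * (1.0 - sleep_efficiency)))
    n_wake = min(max(n_wake, 0), n_epochs - 1) if n_epochs > 1 else n_wake
    # put roughly half of the wake budget up front as latency, the rest as
    # short awakenings scattered through the night
    latency = n_wake // 2
    stages = ["W"] * latency
    scattered = n_wake - latency
    remaining = n_epochs - latency
    wake_positions = set(
        rng.choice(remaining, size=min(scattered, remaining), replace=False)
        if scattered > 0
        else []
    )
    # a plausible NREM/REM cycle, 90 min period
    cycle = ["N1", "N2", "N2", "N3", "N3", "N2", "REM"]
    k = 0
    for i in range(remaining):
        if i in wake_positions:
            stages.append("W")
        else:
            stages.append(cycle[(k // 26) % len(cycle)])
            k += 1
    return Hypnogram(tuple(stages))


def _sleep_runs(hyp: Hypnogram) -> list[tuple[float, float]]:
    """Maximal [start_s, end_s) runs of contiguous non-wake epochs."""
    runs = []
    start = None
    for i, st in enumerate(hyp.epochs):
        if st != "W" and start is None:
            start = i
        elif st == "W" and start is not None:
            runs.append((start * EPOCH_S, i * EPOCH_S))
            start = None
    if start is not None:
        runs.append((start * EPOCH_S, len(hyp.epochs) * EPOCH_S))
    return runs


def _place_events(
    n_events: int,
    hyp: Hypnogram,
    spec: CohortSpec,
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> list[EventInterval]:
    """Poisson-like placement inside sleep, rejection-sampled so events never
    overlap and keep >= 10 s gaps."""
    runs = _sleep_runs(hyp)
    if not runs and n_events > 0:
        raise SimulationError("infeasible: events requested but no sleep epochs")
    placed: list[tuple[float, float]] = []
    labels: list[str] = []
    lo_d, hi_d = spec.event_duration_s
    tries = 0
    while len(placed) < n_events:
        tries += 1
        if tries > max_tries:
            raise SimulationError(
                f"infeasible: placed {len(placed)}/{n_events} events; "
                "target AHI exceeds sleep-time capacity"
            )
        dur = rng.uniform(lo_d, hi_d)
        run = runs[rng.integers(len(runs))]
        if run[1] - run[0] < dur:
            continue
        start = rng.uniform(run[0], run[1] - dur)
        end = start + dur
        if any(start < e + 10.0 and end > s - 10.0 for s, e in placed):
            continue
        placed.append((start, end))
        labels.append(_CLASSES[rng.choice(3, p=spec.class_mix)])
    order = np.argsort([s for s, _ in placed])
    out = []
    for i in order:
        start = round(placed[i][0], 3)
        dur = max(round(placed[i][1] - placed[i][0], 3), 10.0)
        out.append(EventInterval(start, start + dur, label=labels[i]))
    return out


def _breathing_baseline(
    n: int, rate: float, spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rate- and amplitude-modulated sinusoid; returns (effort, phase)."""
    t = np.arange(n) / rate
    f_lo, f_hi = spec.breathing_band_hz
    f_mid = 0.5 * (f_lo + f_hi)
    f_dev = 0.5 * (f_hi - f_lo)
    # slow random drift of the instantaneous rate within the band
    drift = np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
    freq = f_mid + f_dev * drift
    phase = 2 * np.pi * np.cumsum(freq) / rate
    amp = 1.0 + 0.15 * np.sin(2 * np.pi * 0.008 * t + rng.uniform(0, 2 * np.pi))
    return amp * np.sin(phase), phase


def _event_envelope(
    n: int, rate: float, events: Sequence[EventInterval], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample amplitude scale plus an obstructive-distortion mask.

    Hypopnea scales effort to 30-70% of baseline, central apnea to <= 5%,
    obstructive apnea to 20-50%; 2-s cosine ramps avoid step edges.
    """
    scale = np.ones(n)
    distort = np.zeros(n, dtype=bool)
    ramp_s = 2.0
    t = np.arange(n) / rate
    for ev in events:
        if ev.label == "H":
            depth = rng.uniform(0.30, 0.70)
        elif ev.label == "CA":
            depth = rng.uniform(0.0, 0.05)
        else:  # OA: persistent but reduced, distorted effort
            depth = rng.uniform(0.20, 0.50)
        inside = (t >= ev.start_s) & (t < ev.end_s)
        w = np.zeros(n)
        w[inside] = 1.0
        # cosine ramps at the edges
        lead = (t >= ev.start_s) & (t < ev.start_s + ramp_s)
        trail = (t >= ev.end_s - ramp_s) & (t < ev.end_s)
        w[lead] = 0.5 - 0.5 * np.cos(np.pi * (t[lead] - ev.start_s) / ramp_s)
        w[trail] = 0.5 - 0.5 * np.cos(np.pi * (ev.end_s - t[trail]) / ramp_s)
        scale = np.minimum(scale, 1.0 - w * (1.0 - depth))
        if ev.label == "OA":
            distort |= inside
    return scale, distort


def generate_recording(spec: CohortSpec, participant_seed: int) -> RespRecording:
    """Simulate one full recording: trace + annotations + hypnogram.

    Deterministic given ``(spec.seed, participant_seed)``.
    """
    rng = np.random.default_rng([spec.seed, participant_seed])
    rate = spec.rate_hz
    n = int(round(spec.duration_s * rate))
    n_epochs = int(spec.duration_s // EPOCH_S)

    sleep_eff = rng.uniform(*spec.sleep_efficiency_range)
    hyp = _make_hypnogram(n_epochs, sleep_eff, rng)
    tst_h = hyp.total_sleep_time_s / 3600.0

    target_ahi = rng.uniform(*spec.ahi_range)
    n_events = int(round(target_ahi * tst_h))
    events = _place_events(n_events, hyp, spec, rng)

    effort, phase = _breathing_baseline(n, rate, spec, rng)
    scale, distort = _event_envelope(n, rate, events, rng)
    trace = effort * scale
    # obstructive distortion: flattened, harmonic-rich effort
    if distort.any():
        distorted = np.tanh(2.0 * np.sin(phase)) + 0.3 * np.sin(2 * phase)
        trace[distort] = (scale * distorted)[distort]

    # wake: irregular high-variance body motion replacing tidal breathing
    sleep_mask_1hz = hyp.sleep_mask_1hz(int(math.ceil(spec.duration_s)))
    t_idx = np.minimum((np.arange(n) / rate).astype(int), sleep_mask_1hz.size - 1)
    wake = ~sleep_mask_1hz[t_idx]
    if wake.any():
        steps = rng.normal(0, 1.0, size=n)
        walk = np.cumsum(steps) / np.sqrt(rate)
        # high-pass the walk so it wanders around zero on a ~20 s scale
        kernel = int(20 * rate)
        walk = walk - np.convolve(walk, np.ones(kernel) / kernel, mode="same")
        trace[wake] = 1.5 * walk[wake]

    trace = trace + rng.normal(0, spec.noise_sd, size=n)
    return RespRecording(
        id=f"sim{participant_seed:03d}",
        trace=trace,
        rate_hz=rate,
        events=events,
        hypnogram=hyp,
    )


def generate_cohort(spec: CohortSpec) -> list[RespRecording]:
    """Simulate ``spec.n_participants`` recordings (seeds 0..n-1)."""
    return [generate_recording(spec, i) for i in range(spec.n_participants)]


def true_ahi(rec: RespRecording) -> float:
    """Reference AHI of a recording from its annotations and hypnogram."""
    tst_s = rec.hypnogram.total_sleep_time_s
    if tst_s <= 0:
        raise SimulationError("zero total sleep time")
    return len(rec.events) / (tst_s / 3600.0)


def chest_displacement(
    trace: Sequence[float], amplitude_m: float = 0.002
) -> np.ndarray:
    """Map a unit-scale effort trace to chest displacement in meters."""
    trace = np.asarray(trace, dtype=float)
    peak = np.max(np.abs(trace)) or 1.0
    return amplitude_m * trace / peak


def generate_iq(
    chest_displacement_trace: Sequence[float],
    rate: float,
    snr_db: float = np.inf,
    iq_offset: complex = 0.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> IQSeries:
    """Radar IQ from chest displacement: ``A exp(i 4 pi d / lambda) + offset``.

    ``snr_db`` adds complex white noise relative to the carrier amplitude;
    ``inf`` means noiseless.
    """
    d = np.asarray(chest_displacement_trace, dtype=float)
    z = amplitude * np.exp(1j * 4.0 * np.pi * d / WAVELENGTH_M) + iq_offset
    if np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        noise_sd = amplitude / (10.0 ** (snr_db / 20.0)) / np.sqrt(2.0)
        z = z + noise_sd * (
            rng.normal(size=d.size) + 1j * rng.normal(size=d.size)
        )
    return IQSeries(z, rate)
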