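# Methods

This note documents the models and procedures implemented in
`radarsleep`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Radar demodulation

An FMCW radar measures range from the beat frequency of each chirp and
motion from the chirp-to-chirp (slow-time) evolution of the complex
sample at a fixed range bin.  `select_target_bin` averages the fast-time
FFT magnitude over chirps and picks the strongest bin, excluding DC so
static clutter cannot lock the selection; all-zero (or DC-only) input is
an error rather than a silent bin 0.

Chest displacement d(t) moves the slow-time sample around a circle:
z_k ≈ A·exp(i·4π·d_k/λ) + c, with λ = 5 mm at 60 GHz and c an unknown
center offset contributed by IQ gain/offset mismatch and static
reflections.  Phase demodulation (`unwrap(angle(z))`) assumes c = 0 and
distorts badly once |c| is comparable to A.  The implemented
*vector-difference* demodulator instead accumulates signed chord lengths:

    y_0 = 0,   y_k = y_{k−1} + s_k·|z_k − z_{k−1}|

Because only differences enter, a constant offset cancels identically.
The sign rule, which the underlying idea leaves open, is resolved as:
remove the trajectory centroid (z′ = z − mean z), then
s_k = sign(arg(z′_k · conj(z′_{k−1}))), carrying the previous sign when
the rotation angle is exactly zero and starting at +1.  For points on a
circle, the angle seen from any interior point is monotone along the
arc, so this reproduces forward/backward chest motion antisymmetrically.
On noiseless synthetic IQ the recovered trace correlates with the true
displacement at |r| > 0.999, and the test suite checks bit-identical
output under trajectory offsets constructed on a dyadic float grid
(where the offset arithmetic is exact).

Low-pass filtering before demodulation is a 4th-order Butterworth at
2 Hz applied forward-backward (`sosfiltfilt`), i.e. zero phase, because
respiration lives below ~1 Hz and group delay would shift event onsets.
The cutoff and order are package choices; nothing in the method depends
on them strongly as long as the breathing band passes untouched
(amplitude error < 1% at 0.25 Hz) and noise above ~4 Hz is suppressed
(≥ 20 dB by 2× the cutoff).

## Preprocessing

The effort trace is resampled from its native 1000/33 Hz (≈ 30.3 Hz) to
8 Hz with Fourier resampling (`scipy.signal.resample`); output length is
round(duration × 8).  Windows are 60 s (480 samples) with a 30-s stride,
so consecutive windows share exactly 30 s; a trailing partial window is
dropped rather than padded, keeping the network input size fixed.  Each
window is z-scored on its own mean and SD; an exactly flat window maps
to zeros.

Reference events are rasterized to 1 Hz by the midpoint rule: second t
belongs to the event covering t + 0.5 s.  When events overlap, the
priority is obstructive apnea > central apnea > hypopnea (rarest and most
specific win).  A window is *abnormal* when some run of ≥ 10 consecutive
seconds is non-Normal — deliberately the same 10-s floor the clinical
scoring rules apply to events themselves.  For multiclass labels the
window class is the dominant class of the longest qualifying run, with
ties going to the earlier run.  The midpoint rule, the priority order
and the tie-breaks are package choices made for determinism; a
brute-force per-second oracle in the tests pins the exact semantics.

## The CRNN detector

The detector maps one z-scored 480-sample window to 60 per-second class
probability vectors — dense (strong-label) detection rather than
window-level classification, so the 1-s annotation resolution is used
directly.

Architecture (fixed by `ModelConfig`):

| stage | details |
|---|---|
| 4 conv blocks | each: 2 × (conv1d 64 filters, width 3, stride 1, same padding → batch-norm → ReLU), then max-pool (window 2) and dropout 0.2 |
| pooling strides | (2, 2, 2, 1) — product 8, so 480 samples → 60 frames at exactly the 1-Hz label rate; any configuration whose pool product ≠ 8 is rejected at construction |
| recurrent | bidirectional LSTM, 128 units per direction, full BPTT over the 60 frames |
| head | frame-wise dense 128 + ReLU + dropout, dense n_classes, softmax per frame |

The loss is frame-wise cross-entropy plus soft Dice: for class c over
all frames in the batch, D_c = (2·Σ p·t + ε)/(Σ p + Σ t + ε) with
smoothing ε = 1, and the Dice term is 1 − mean_c D_c.  The Dice
formulation (per class over frames, batch-pooled, ε = 1) follows common
segmentation practice; the cross-entropy term is averaged over frames so
the two terms have comparable scale.

The network, backpropagation (including through the BiLSTM), the loss
gradient and Adam are implemented directly on NumPy arrays.  Convolution
is an im2col matrix product; arithmetic is float32 by default with a
float64 switch used by the gradient tests, which check every layer's
analytic gradient against central differences at 1e-4 relative
tolerance.  Dropout is inverted and disabled at inference, so repeated
inference is bit-identical; initialization is Glorot-uniform from a
seeded generator, so a seed fully determines the model.

## Training

Splits are by *participant*: `make_folds` randomly partitions recording
ids into five folds differing in size by at most one, and `train_fold`
refuses any split where an id appears on both sides.  The optimizer is
Adam at 1e-3 with batch 64; the learning rate halves when validation
loss fails to improve by more than 1e-4 for 10 consecutive epochs, early
stopping fires after 25 such epochs, the cap is 100 epochs, and the
best-validation weights are restored at the end.  The 1e-4 min-delta and
best-weight restoration are package choices.  Training segments are
reshuffled every epoch from the run seed.  Folds are not stratified by
OSA severity (no stratification flag is set by default).

## Evaluation

**Per segment.**  The predicted score of a window is the minimum
threshold at which its 1-Hz abnormal track (1 − P(Normal)) still shows
10 consecutive above-threshold seconds; computationally, the maximum
over all 51 ten-frame windows of the within-window minimum.  "Above
threshold" is ≥, so a window always fires at its own score.  Scores are
evaluated with the Mann-Whitney AUROC (ties counted half) and DeLong
structural-component variance for the 95% CI; group comparisons (e.g.
severe vs rest) use the unpaired DeLong z-test, appropriate because the
groups contain disjoint participants.  The operating point maximizes the
Youden index over observed score values (ties → lower cutoff), and
count metrics carry Wilson 95% intervals — the binomial CI family is a
package choice and is labeled in the output.  Severity-group rows reuse
the overall cutoff so their confusion counts partition the overall ones.

**Per event.**  Because windows overlap by 30 s, each second of a night
is covered by one or two windows; the night track averages the available
predictions.  Events are maximal runs of track ≥ θ lasting ≥ 10 s,
matched one-to-one to reference events greedily in descending-IoU order
at IoU ≥ 0.5 (a standard, deterministic detection-matching rule; the
matching discipline when several detections overlap one truth is
otherwise open).  θ is chosen on a 0.01 grid to maximize F1 pooled over
the whole cohort (pooled rather than per-participant — another open
point resolved here), ties to the lower θ.  False positives per
participant are reported both for all detections and after the
*in-sleep* filter, which keeps an event only if strictly more than half
of its seconds fall in non-wake hypnogram epochs (a 20-s event with
exactly 10 s of sleep is removed).

**Per patient.**  AHI = detected events / total sleep time in hours,
with TST taken from the reference hypnogram for both the estimate and
the ground truth, so the comparison isolates event detection.  The
corrected AHI counts only in-sleep events and can only be ≤ the
uncorrected one.  Agreement: Pearson r; ICC(2,1) — two-way random
effects, absolute agreement, single measurement (the ICC form is a
package choice, computed via pingouin and pinned to a closed-form ANOVA
oracle in the tests); Bland-Altman bias with a t-based CI and
bias ± 1.96·SD limits of agreement; and linearly weighted kappa over the
four severity classes (scikit-learn, pinned to the weight-matrix closed
form).

## Synthetic cohort

The simulator generates what the pipeline consumes — trace, annotations,
hypnogram, optionally raw IQ — with the statistical structure the
detector relies on:

- breathing: a sinusoid with slowly drifting rate inside 0.2–0.3 Hz and
  ±15% amplitude modulation;
- hypopnea: amplitude scaled to 30–70% of the local baseline (the radar
  sees *effort*, not airflow, so the clinical ≥30% airflow-reduction
  definition is transferred to effort amplitude);
- obstructive apnea: persistent but reduced (20–50%) effort with
  waveform distortion (saturated fundamental plus second harmonic) —
  effort continues against an obstructed airway;
- central apnea: near-absent effort (≤ 5%);
- events last 10–60 s with 2-s cosine ramps, are placed by rejection
  sampling inside contiguous sleep, never overlap and keep ≥ 10-s gaps;
  the per-participant event count is target AHI × TST;
- class mix H/OA/CA = 0.710/0.266/0.024, the composition observed in
  clinical event inventories (hypopnea-dominant, central apnea rare);
- wake epochs carry irregular high-variance motion (a high-passed random
  walk), and Gaussian sensor noise (SD 0.1 of unit effort) is added
  everywhere;
- hypnograms have a sleep-latency wake block, scattered awakenings
  matching the drawn sleep efficiency (uniform 0.65–0.95), and a 90-min
  NREM/REM cycle;
- IQ synthesis: z = A·exp(i·4π·d/λ) + offset + complex white noise,
  λ = 5 mm.

Defaults are 20 participants × 2 h with target AHI uniform over 0–60
events/h.  Everything is a pure function of (cohort seed, participant
seed).

**What the simulator does not emulate** — and hence what passing tests
do *not* show about clinical data: body-position changes and limb
movements, arousal-linked amplitude dynamics, oxygen desaturation,
scorer disagreement, radar clutter/multipath (noise is white Gaussian),
and the hard class overlap between mild hypopnea and normal-breathing
variability.  Synthetic events are well separated in amplitude, so
detection metrics on this cohort are far higher than any clinical cohort
would yield; the end-to-end tests demonstrate that the pipeline is
correct and learnable, not that the clinical problem is solved.

## Problem sizes in the checks

The end-to-end acceptance check and `scripts/acceptance.py` run the full
train-and-evaluate cycle on a 16-participant cohort of 40-min recordings
(≈ 1 260 windows), training for up to 12 epochs under the plateau
schedule, with held-out participants chosen to span the AHI range; the
test averages the held-out segment AUROC over three training seeds.
These sizes are the package's chosen benchmark conditions for a
single-CPU run; the architecture, schedule logic, and all thresholds are
identical to the full-scale configuration.

## Known limitations

- The NumPy network trains on CPU only and is ~an order of magnitude
  slower than a GPU framework; full 100-epoch runs on multi-hour cohorts
  are possible but slow.
- Event *class* is not predicted per detected event; like the evaluation
  design it follows, all detection and AHI metrics collapse the three
  event classes to one abnormal class (per-class sensitivity is still
  reported through the class of the matched reference event).
- EDF reading requires `mne` (optional); the canonical interchange
  format is CSV.
- Mixed-apnea labels are not modeled; unknown labels can be mapped to OA
  or dropped by configuration.
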