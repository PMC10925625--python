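# Methods

## The measurement problem

Two devices observe the same physical event — an eye blink — through
different paths: the VR headset's eye tracker samples eyelid openness at
120 Hz internally and its host software re-emits the stream at 250 Hz,
while the EEG/EMG amplifier records a periocular EMG channel at 500 Hz.
Stream middleware aligns the receive-side clocks but cannot observe the
device-internal and transport latencies, which differ between the two
paths by a roughly constant *offset* plus per-event *jitter*. Any analysis
that locks EEG epochs to eye-tracker (or stimulus) events inherits this
error, so it must be measured once per setup and corrected.

## Offset estimator

Pipeline (per recording):

1. **Dejitter.** Timestamps are replaced by an ordinary-least-squares line
   fit of timestamp on sample index. OLS is the conventional choice for
   regularizing arrival-time jitter around a stable hardware clock; a
   Theil–Sen option (`dejitter_method="theil-sen"`) is available for
   streams with gross stamp outliers. The fit preserves the mean
   timestamp, is idempotent, and is exactly equivariant under time shifts
   — the last point matters because the quantity being estimated *is* a
   time shift.
2. **Resample.** Any stream above the 250 Hz analysis rate is decimated
   after a zero-phase order-8 Butterworth low-pass at 0.45 × target rate.
   Zero-phase (forward–backward) application is non-negotiable here: a
   causal anti-alias filter would add a group delay of the same order as
   the offset being measured.
3. **Eye landmark.** First sample of each maximal run of 1s in
   `both_blinking`; when that channel is absent it is derived as
   min(left, right openness) < 0.1. The threshold is strict (openness of
   exactly 0.1 counts as open), matching the device's definition.
4. **EMG landmark.** The whole EMG channel is band-passed 0.75–5 Hz
   (3rd-order Butterworth, forward–backward). Within a ±0.5 s window
   around each eye onset, the landmark is the first index at or before
   the window maximum where the signal reaches 90% of that maximum. A
   leading-edge landmark is invariant to amplitude scaling and robust to
   plateaued peaks; ties between equal maxima resolve to the earliest.
5. **Validity.** A window is `truncated` if its padding leaves the
   recording; `distorted_emg` if it holds ≥ 2 peaks each above 70% of the
   window maximum separated by > 200 ms, or if its maximum is below 5 ×
   the filtered channel's median absolute amplitude (no discernible
   burst). All three thresholds are configurable; they are heuristics
   standing in for visual curve inspection.
6. **Aggregation.** Mean and sample STD over valid blinks; a single
   (not iterated) exclusion pass drops blinks beyond 3 × STD of the mean,
   then the statistics are recomputed. The retained STD is reported as
   jitter.
7. **Trimming (multi-recording sessions).** Recordings of one session may
   hold different blink counts; candidate strategies {none, head, tail,
   symmetric} trim each recording's blink list to the shortest common
   count, and the strategy with minimal pooled STD wins (ties to the
   first listed).

Sign convention: positive offset = the eye tracker registered the blink
*earlier* than the EMG landmark. Correction therefore delays eye-tracker
timestamps by the offset. Milliseconds are Δindex × 1000 / rate; at
250 Hz, 9 samples ≙ 36 ms.

### Resolution limits

The eye tracker's native frame is 1/120 s ≈ 8.33 ms, so a single blink's
eye landmark is quantized to that grid, and the re-emission at 250 Hz
adds a second, smaller quantization (≤ 4 ms). Consequences:

* the mean offset over many blinks with uniformly distributed grid phase
  is recoverable to well within one device frame (the residual bias of
  the full pipeline measures ≈ −4 ms: detection always waits for the
  *next* grid tick on the eye side, partly cancelled by the same effect
  at 250 Hz on the EMG side);
* even a perfectly constant hardware offset shows a jitter floor. The
  composite quantization yields a per-recording STD between about 2 and
  4.3 ms depending on the relative phase of the 120 Hz and 250 Hz grids
  — comfortably below the method's 9 ms jitter budget, and consistent
  with real-hardware sessions reporting minima near 6 ms.

Tolerances in the test suite are therefore expressed in units of the
8.33 ms device frame, not of the 250 Hz analysis grid.

## SSVEP decoder

Preprocessing reflects each channel about its edges (0.5 s padding),
applies a 50 Hz IIR notch (Q = 30) and a 1–15 Hz 3rd-order Butterworth,
both forward–backward, and removes the padding — length-preserving and
zero-phase. References for candidate frequency f are sin/cos pairs at f
and 2f, phase zero at flicker onset; a third harmonic would fall outside
(or on the shoulder of) the 1–15 Hz band for the upper frequencies, so
`n_harmonics` defaults to 2. The decision statistic is the largest
canonical correlation between the multichannel epoch and each reference
set, computed from the covariance blocks by Cholesky whitening and SVD
with a ridge of 1e-8 × (mean diagonal) on the auto-covariances for
stability on short epochs; ties in the argmax resolve to the lower
frequency. CCA makes the decoder phase-insensitive and calibration-free,
which is also why the paradigm tolerates residual synchronization error:
the epoch shift only needs to be right to within a fraction of the
flicker period, not of a sample.

Epoch alignment: epoch start = flicker onset (stimulus/eye clock)
+ hardware offset + ocular conduction delay. The delay defaults to
100 ms, the standard retina-to-V1 conduction allowance; it is applied as
a pure window shift before preprocessing.

ITR uses the Wolpaw formula with N = 30 targets by default (a full
keyboard reachable because gaze pre-selects the six-letter cluster, so
six flicker frequencies address thirty letters) and T = the flicker
period. Both are explicit parameters: published ITRs depend strongly on
whether gaze time and inter-trial gaps are charged to T, and on whether N
counts frequencies or letters, so no single default reproduces any
particular published table.

## Synthetic sessions

The blink generator emulates the acquisition protocol the estimator is
designed for: blinks paced at 60 BPM in sets of 10–20 (default 20), an
eyelid trace that closes linearly over 30 ms (crossing the 0.1 threshold
at the true closure instant), holds shut 70 ms and reopens over 80 ms,
sampled on a 120 Hz device grid with uniform random phase and re-emitted
at 250 Hz by sample-and-hold; and an EMG raised-cosine burst (150 ms)
at 500 Hz. Three deliberate modelling choices:

* **Per-blink grid phase.** At exactly 60 BPM every blink would hit the
  same 120 Hz grid phase (1 s is an integer number of frames), nulling
  the quantization variability the generator exists to exhibit; each
  closure instant therefore carries a U(0, 1/120 s) draw, modelling that
  human pacing does not lock to an 8 ms grid.
* **Jitter placement.** Injected Gaussian jitter is applied to the
  per-blink *inter-stream latency* (the EMG landmark lands at closure +
  offset + jitter_k). Jitter applied to the closure instant itself would
  shift both streams together and cancel identically — hardware jitter is
  transport variability between the streams, not blink-time variability.
* **Self-calibrated burst placement.** The 0.75–5 Hz band-pass reshapes a
  150 ms burst and moves its 90% rising crossing; the generator filters a
  noiseless burst train once, measures the mean crossing error, and
  shifts all bursts to compensate, so the *filtered* landmark lands at
  closure + offset by construction (continuous time), leaving only
  sampling quantization between ground truth and estimate.

The SSVEP generator sums the stimulus fundamental and a half-amplitude
second harmonic with a seeded random phase, mixes it across 8 channels by
seeded random weights, and adds per-channel 1/f noise (exponent 1) plus a
50 Hz line component, scaled so that signal/noise power within the
1–15 Hz band matches the requested SNR in dB; `snr_db=None` is noiseless.

What the simulators do *not* model — and hence what passing tests do not
establish about real data: real blink EMG morphology and its
participant-to-participant variability (the raised cosine is chosen for
an analytically locatable landmark, and the double-peak distortion
injected by `distortion_fraction` is a labelled synthetic stand-in, not a
physiological artifact taxonomy), volume conduction and correlated noise
across EEG channels, eye-tracker dropouts and partial closures, clock
drift between devices (offset is modelled as constant plus white jitter),
and any gaze dynamics. Recovery of a 36 ms synthetic offset shows the
estimator's arithmetic and its quantization behaviour are right, not that
any particular hardware has a 36 ms offset.

## Numerical and scale choices

* Filters are SOS-form Butterworth, applied with `sosfiltfilt`; epochs
  shorter than the padding, or than the filter's stable minimum, raise
  rather than silently truncating.
* Degenerate CCA covariances beyond ridge rescue raise
  `degenerate covariance`; correlations are clipped to [0, 1] against
  roundoff.
* The default simulation sizes used in the test suite and acceptance
  script — 100–500 blinks per estimator run, 30–120 SSVEP epochs per
  sweep — are chosen so that binomial/quantization sampling error is
  well inside the asserted tolerances while a full run stays in the tens
  of seconds on one CPU.
* CSV recordings store floats with 17 significant digits (exact
  round-trip); timestamps compare to 1e-9 s in tests. XDF is read via the
  optional `pyxdf` dependency; there is no XDF writer.
* Offsets are reported to 0.01 ms. That is a report precision, not an
  accuracy claim — accuracy is bounded by the 8.33 ms device frame.

## Known limitations

* The estimator assumes at least two valid blinks and errors otherwise;
  it does not attempt single-blink inference.
* Constant-offset model: no drift tracking over long sessions.
* The distortion detector's thresholds (70% twin-peak, 200 ms separation,
  5 × median amplitude floor) are heuristics; on real data they should be
  reviewed against example curves before being trusted.
* Gaze-based cluster pre-selection is metadata only; no gaze geometry or
  dwell logic is implemented.
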