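# vrsync

Synchronizing an EEG/EMG amplifier with the eye tracker built into a
consumer VR headset — and proving the synchronization is good enough to
drive a brain-computer interface.

Middleware such as LabStreamingLayer puts concurrently recorded streams on
one clock, but it cannot see the latency inside each device or its
transport path. `vrsync` measures that residual hardware offset with a
purely biological marker: paced eye blinks, which appear both as the onset
of the eye tracker's `both_blinking` flag and as a burst on a periocular
EMG channel. It also ships the canonical downstream consumer — an SSVEP
(steady-state visually evoked potential) speller classifier based on
canonical correlation analysis (CCA) — and a simulator that generates
blink sessions and SSVEP epochs with known ground truth, so the entire
pipeline is testable without any hardware.

Intended users: BCI / cognitive-neuroscience groups combining commodity
EEG amplifiers with VR-integrated eye tracking, and anyone who needs to
quantify inter-stream latency and jitter before trusting event-locked
analyses.

## The method

**Offset estimation.** Per blink, the eye-side landmark is the first
sample at which `both_blinking` becomes 1 (the device reports an eye as
closed when eyelid openness < 0.1); the EMG-side landmark is the first
rising crossing of 90% of the burst maximum after a zero-phase Butterworth
band-pass (0.75–5 Hz, 3rd order). Both streams are dejittered (timestamps
regularized by a least-squares linear clock fit) and brought to a common
analysis rate of 250 Hz, so an index difference Δk converts to

&nbsp;&nbsp;&nbsp;&nbsp;offset = Δk · 1000 / 250 ms  (9 samples ≙ 36 ms).

Blinks with distorted EMG bursts (multiple comparable peaks, or no burst)
are excluded, as are offsets farther than 3·STD from the mean (single
pass). The session estimate is the mean over retained blinks; its STD is
the jitter. Because the eye tracker samples at 120 Hz, no estimate can be
more accurate than one device frame, 1/120 s ≈ 8.33 ms; the sampling-grid
quantization alone produces a jitter floor of a few milliseconds even when
the true offset is perfectly constant.

**SSVEP classification.** Occipito-parietal channels (O1, Oz, O2, P3, P7,
Pz, P8, P4) are notch-filtered at 50 Hz and band-passed 1–15 Hz
(zero-phase, 3rd order, reflect-padded). An epoch X recorded during a
flicker period is compared against sinusoidal references
Y_f = [sin 2πhft, cos 2πhft], h = 1..2, for each candidate frequency
f ∈ {4, 5, 5.5, 6, 7, 7.4} Hz; the prediction is
argmax_f ρ_max(X, Y_f), the largest canonical correlation. Epochs are cut
starting at flicker onset + hardware offset + 100 ms ocular conduction
delay. Sessions are scored by accuracy and the Wolpaw information
transfer rate ITR = (60/T)·[log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))].

## Worked example

Simulate a paced-blink session (20 blinks at 60 BPM, true offset 36 ms)
and estimate the offset back:

```
$ vrsync simulate blinks --params blinks.yaml --out rec --truth truth.json
$ vrsync measure-offset rec --report offset.json
Blink-based stream offset estimate
==================================
mean offset             32.60 ms
jitter (STD)             2.68 ms
SEM                      0.60 ms
95% CI             [31.42, 33.78] ms
blinks used                20
blinks excluded             0
trimming strategy        none
```

The estimate lands within one 120 Hz device frame (8.33 ms) of the
injected 36 ms — the best any estimator can promise at this device
granularity — and the 2.68 ms jitter is pure sampling-grid quantization,
well under the 9 ms the method budgets. The same works from Python:

```python
from vrsync import BlinkOffsetModel, BlinkSimParams, simulate_blink_recording

rec, truth = simulate_blink_recording(BlinkSimParams(n_blinks=20, seed=42))
res = BlinkOffsetModel(rec).fit()
print(res.summary())          # the table above
res.mean_offset_ms, res.std_ms
```

and for the speller side:

```python
from vrsync import SsvepDecoder, SsvepSimParams, simulate_ssvep_trial

trial = simulate_ssvep_trial(SsvepSimParams(freq=6.0, flicker_period=4.0))
trial.predicted_freq          # 6.0 — noiseless epochs decode exactly
```

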