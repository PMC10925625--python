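"""Synthetic multimodal sessions with known ground truth.

Two generators make the whole pipeline testable without hardware:

* :func:`simulate_blink_recording` emulates a metronome-paced blink
  session: for each blink a true closure instant is drawn, an eyelid
  openness trace crossing the device's 0.1 closure threshold at that
  instant is sampled on the eye tracker's native 120 Hz grid (uniform
  random grid phase) and re-emitted at the 250 Hz transport rate by
  sample-and-hold, and a periocular EMG burst is placed so that its
  band-pass-filtered 90%-rising-crossing lands a configurable true offset
  (plus optional Gaussian per-blink latency jitter) later. The 120 Hz grid
  is what produces the quantization-jitter floor a
  real session shows even with a perfectly constant hardware offset.

* :func:`simulate_ssvep_trial` emulates one flicker period: a stimulus
  sinusoid plus harmonics, mixed across channels, embedded in 1/f
  ("pink") background EEG and 50 Hz mains interference at a configurable
  in-band signal-to-noise ratio.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .streams import EYE_CHANNELS, Recording, TimedStream


class SynthError(ValueError):
    """Raised for invalid simulation parameters."""


# ---------------------------------------------------------------------------
# Colored noise
# ---------------------------------------------------------------------------

def make_colored_noise(
    n_samples: int,
    rate: float,
    exponent: float = 1.0,
    line_amp: float = 0.0,
    seed: int | np.random.Generator = 0,
    line_hz: float = 50.0,
) -> np.ndarray:
    """1/f^exponent noise, unit variance, plus an optional mains sinusoid.

    The power spectral density is shaped in the frequency domain
    (S(f) ∝ f^-exponent, DC removed), the series normalized to zero mean
    and unit variance, and a fixed-amplitude sinusoid at *line_hz* with a
    seeded random phase added afterwards.
    """
    if n_samples < 2:
        raise SynthError("need at least 2 samples of noise")
    if not (0 <= exponent <= 2):
        raise SynthError(f"spectral exponent {exponent} outside [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    phase = rng.uniform(0, 2 * np.pi)
    if exponent > 0:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
        scale = np.ones_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        scale[0] = 0.0
        x = np.fft.irfft(spec * scale, n=n_samples)
    else:
        x = white
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    if line_amp:
        t = np.arange(n_samples) / rate
        x = x + line_amp * np.sin(2 * np.pi * line_hz * t + phase)
    return x


# ---------------------------------------------------------------------------
# Blink sessions
# ---------------------------------------------------------------------------

@dataclass
class BlinkSimParams:
    """Ground-truth parameters of a synthetic blink session.

    Defaults mirror the acquisition protocol the estimator is meant for:
    blinks paced by a metronome at 60 BPM in sets of 10–20, the eye
    tracker sampling at 120 Hz and transmitting at 250 Hz, the EMG
    amplifier at 500 Hz. ``true_offset_ms`` is positive when the
    eye-tracker stream registers the blink before the EMG landmark.
    """

    n_blinks: int = 20
    pace_bpm: float = 60.0
    true_offset_ms: float = 36.0
    jitter_sd_ms: float = 0.0
    eye_device_rate: float = 120.0
    stream_rate: float = 250.0
    emg_rate: float = 500.0
    blink_duration_ms: float = 150.0
    closure_threshold: float = 0.1
    eye_fall_ms: float = 30.0
    eye_hold_ms: float = 70.0
    eye_reopen_ms: float = 80.0
    emg_noise: float = 0.005
    distortion_fraction: float = 0.0
    lead_in_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blinks < 1:
            raise SynthError("need at least 1 blink")
        if min(self.eye_device_rate, self.stream_rate, self.emg_rate) <= 0:
            raise SynthError("sampling rates must be positive")
        if self.jitter_sd_ms < 0:
            raise SynthError("jitter SD must be >= 0")
        pace_s = 60.0 / self.pace_bpm
        busy = (
            self.blink_duration_ms / 1000.0,
            (self.eye_fall_ms + self.eye_hold_ms + self.eye_reopen_ms) / 1000.0,
        )
        if max(busy) >= pace_s:
            raise SynthError(
                f"blinks overlap: blink of {max(busy) * 1000:.0f} ms at "
                f"{self.pace_bpm} BPM pacing"
            )


def _openness_trace(t: np.ndarray, closures: np.ndarray, p: BlinkSimParams) -> np.ndarray:
    """Continuous eyelid openness: linear close, hold shut, linear reopen.

    The closing ramp is placed so openness crosses ``closure_threshold``
    exactly at each closure instant.
    """
    fall = p.eye_fall_ms / 1000.0
    hold = p.eye_hold_ms / 1000.0
    reopen = p.eye_reopen_ms / 1000.0
    open_v = np.ones_like(t)
    for c in closures:
        # ramp 1 -> 0 over `fall`; value threshold at fraction (1 - thr)
        start = c - (1.0 - p.closure_threshold) * fall
        seg = (t >= start) & (t < start + fall)
        open_v[seg] = np.minimum(open_v[seg], 1.0 - (t[seg] - start) / fall)
        seg = (t >= start + fall) & (t < start + fall + hold)
        open_v[seg] = 0.0
        seg = (t >= start + fall + hold) & (t < start + fall + hold + reopen)
        open_v[seg] = np.minimum(
            1.0, (t[seg] - start - fall - hold) / reopen
        )
    return np.clip(open_v, 0.0, 1.0)


def _raised_cosine(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """0.5 (1 − cos) burst of *duration* seconds beginning at *start*."""
    u = (t - start) / duration
    burst = np.zeros_like(t)
    seg = (u >= 0) & (u <= 1)
    burst[seg] = 0.5 * (1.0 - np.cos(2 * np.pi * u[seg]))
    return burst


def _rising_crossing_time(
    y: np.ndarray, t: np.ndarray, lo: int, hi: int, fraction: float
) -> float:
    """Continuous-time first crossing of fraction × max within y[lo:hi]."""
    w = y[lo:hi]
    imax = int(np.argmax(w))
    thresh = fraction * w[imax]
    idx = int(np.flatnonzero(w[: imax + 1] >= thresh)[0])
    g = lo + idx
    if idx == 0 or y[g - 1] >= thresh:
        return float(t[g])
    frac = (thresh - y[g - 1]) / (y[g] - y[g - 1])
    return float(t[g - 1] + frac * (t[g] - t[g - 1]))


def _emg_filter_sos(rate: float) -> np.ndarray:
    # same band as the analysis default (0.75–5 Hz, 3rd order)
    return signal.butter(3, (0.75, 5.0), btype="bandpass", fs=rate, output="sos")


def simulate_blink_recording(p: BlinkSimParams) -> tuple[Recording, dict]:
    """Synthesize one paced-blink session and its ground truth.

    Returns a :class:`Recording` with an ``eye`` stream (five channels at
    the transport rate, sample-and-hold from the 120 Hz device grid) and
    an ``emg`` stream (one channel at the amplifier rate), plus a ground
    truth dict with per-blink closure instants, jitter draws, grid-phase
    draws, and distortion flags.

    Blink phases relative to the 120 Hz device grid are uniform: exact
    metronome pacing would lock every blink to the same grid phase
    (1 s is an integer number of 8.33 ms frames), which no human achieves;
    each closure instant therefore carries a U(0, 1/120 s) phase draw in
    addition to any Gaussian jitter.
    """
    rng = np.random.default_rng(p.seed)
    pace_s = 60.0 / p.pace_bpm
    t_metronome = p.lead_in_s + pace_s * np.arange(p.n_blinks)
    grid_step = 1.0 / p.eye_device_rate
    phase_draws = rng.uniform(0.0, grid_step, size=p.n_blinks)
    # jitter is transport/latency variability BETWEEN the streams: the
    # per-blink offset is true_offset + jitter_k. (Jitter on the closure
    # instant itself would shift both streams together and cancel.)
    jitter_draws = rng.normal(0.0, p.jitter_sd_ms / 1000.0, size=p.n_blinks)
    closures = t_metronome + phase_draws
    duration = p.lead_in_s * 2 + pace_s * p.n_blinks
    offset_s = p.true_offset_ms / 1000.0

    # --- eye stream: sample on the device grid, re-emit by sample-and-hold
    device_phase = rng.uniform(0.0, grid_step)
    t_device = np.arange(device_phase, duration, grid_step)
    openness_dev = _openness_trace(t_device, closures, p)
    t_stream = np.arange(0.0, duration, 1.0 / p.stream_rate)
    hold_idx = np.searchsorted(t_device, t_stream, side="right") - 1
    hold_idx = np.clip(hold_idx, 0, t_device.size - 1)
    openness = openness_dev[hold_idx]
    closed = (openness < p.closure_threshold).astype(float)
    eye_samples = np.column_stack([closed, closed, closed, openness, openness])
    eye = TimedStream(
        name="eye",
        channel_labels=list(EYE_CHANNELS),
        samples=eye_samples,
        nominal_rate=p.stream_rate,
        timestamps=t_stream,
    )

    # --- EMG stream: raised-cosine bursts, self-calibrated placement
    t_emg = np.arange(0.0, duration, 1.0 / p.emg_rate)
    dur = p.blink_duration_ms / 1000.0
    # raw raised cosine reaches 90% of peak at acos(-0.8)/(2π) of its span
    rise_frac = float(np.arccos(-0.8) / (2 * np.pi))
    targets = closures + offset_s + jitter_draws
    starts = targets - rise_frac * dur

    def render(burst_starts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t_emg)
        for s in burst_starts:
            out += _raised_cosine(t_emg, s, dur)
        return out

    # calibration: the analysis band-pass reshapes the burst and shifts its
    # 90% crossing; measure the mean shift on the noiseless train and
    # compensate, so the *filtered* landmark lands at closure + offset.
    sos = _emg_filter_sos(p.emg_rate)
    half = int(round(0.4 * pace_s * p.emg_rate))
    trial = signal.sosfiltfilt(sos, render(starts))
    errs = []
    for tgt in targets:
        center = int(round(tgt * p.emg_rate))
        lo, hi = max(0, center - half), min(t_emg.size, center + half)
        errs.append(_rising_crossing_time(trial, t_emg, lo, hi, 0.9) - tgt)
    starts = starts - float(np.mean(errs))
    emg_clean = render(starts)

    # optional distorted bursts: a late second peak of comparable height
    n_distort = int(round(p.distortion_fraction * p.n_blinks))
    distorted = np.zeros(p.n_blinks, dtype=bool)
    if n_distort:
        which = rng.choice(p.n_blinks, size=n_distort, replace=False)
        distorted[which] = True
        for k in which:
            emg_clean += 0.85 * _raised_cosine(t_emg, starts[k] + 0.30, dur)

    emg_sig = emg_clean + p.emg_noise * rng.standard_normal(t_emg.size)
    emg = TimedStream(
        name="emg",
        channel_labels=["EMG"],
        samples=emg_sig[:, None],
        nominal_rate=p.emg_rate,
        timestamps=t_emg,
    )

    truth = {
        "true_offset_ms": p.true_offset_ms,
        "jitter_sd_ms": p.jitter_sd_ms,
        "closure_instants_s": closures.tolist(),
        "grid_phase_draws_s": phase_draws.tolist(),
        "jitter_draws_s": jitter_draws.tolist(),
        "device_grid_phase_s": float(device_phase),
        "distorted": distorted.tolist(),
        "seed": p.seed,
    }
    rec = Recording(
        streams=[eye, emg],
        metadata={"session_id": f"synthetic-blinks-seed{p.seed}", "synthetic": True},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# SSVEP trials
# ---------------------------------------------------------------------------

@dataclass
class SsvepSimParams:
    """Ground truth for one synthetic SSVEP flicker period.

    ``snr_db`` is the ratio of stimulus-response power to noise power
    within the 1–15 Hz analysis band; ``None`` means noiseless.
    """

    freq: float = 6.0
    flicker_period: float = 4.0
    rate: float = 250.0
    harmonic_amps: tuple[float, ...] = (1.0, 0.5)
    snr_db: float | None = None
    noise_exponent: float = 1.0
    line_amp: float = 1.0
    n_channels: int = 8
    band: tuple[float, float] = (1.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise SynthError("stimulus frequency must be positive")
        if self.freq * len(self.harmonic_amps) >= self.rate / 2:
            raise SynthError(
                f"harmonic {self.freq * len(self.harmonic_amps)} Hz at or "
                f"above Nyquist {self.rate / 2} Hz"
            )


def simulate_ssvep_epoch(p: SsvepSimParams) -> np.ndarray:
    """Raw multichannel epoch: harmonics × channel weights + colored noise."""
    rng = np.random.default_rng(p.seed)
    n = int(round(p.flicker_period * p.rate))
    t = np.arange(n) / p.rate
    phase = rng.uniform(0, 2 * np.pi)
    sig = np.zeros(n)
    for h, amp in enumerate(p.harmonic_amps, start=1):
        sig += amp * np.sin(2 * np.pi * h * p.freq * t + phase)
    weights = rng.uniform(0.5, 1.5, size=p.n_channels)
    epoch = np.outer(sig, weights)
    if p.snr_db is None or np.isinf(p.snr_db):
        return epoch
    noise = np.column_stack(
        [
            make_colored_noise(n, p.rate, p.noise_exponent, p.line_amp, rng)
            for _ in range(p.n_channels)
        ]
    )
    sos = signal.butter(3, p.band, btype="bandpass", fs=p.rate, output="sos")
    sig_band = signal.sosfiltfilt(sos, epoch, axis=0)
    noise_band = signal.sosfiltfilt(sos, noise, axis=0)
    p_sig = float(np.mean(sig_band**2))
    p_noise = float(np.mean(noise_band**2))
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (p.snr_db / 10.0)))
    return epoch + scale * noise


def simulate_ssvep_session(
    freqs: Sequence[float],
    p: SsvepSimParams | None = None,
    gap_s: float = 1.0,
    hardware_offset_ms: float = 0.0,
    ocular_delay_ms: float = 100.0,
    channel_labels: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """A whole test session: one EEG stream plus a flicker-marker stream.

    Each entry of *freqs* is one trial; its marker (flicker onset on the
    stimulus clock) is placed on the marker stream, and the evoked
    response is written into the EEG stream starting ``hardware_offset_ms
    + ocular_delay_ms`` later — the alignment the decoder must undo.
    """
    from .ssvep import DEFAULT_CHANNELS

    p = p or SsvepSimParams()
    labels = list(channel_labels or DEFAULT_CHANNELS)
    n_ch = len(labels)
    n_epoch = int(round(p.flicker_period * p.rate))
    slot = p.flicker_period + gap_s
    lead = 2.0
    duration = lead + slot * len(freqs) + lead
    n_total = int(round(duration * p.rate))
    t = np.arange(n_total) / p.rate
    eeg = np.zeros((n_total, n_ch))
    delay_s = (hardware_offset_ms + ocular_delay_ms) / 1000.0
    onsets = []
    for k, f in enumerate(freqs):
        onset = lead + k * slot
        trial_p = SsvepSimParams(
            freq=float(f),
            flicker_period=p.flicker_period,
            rate=p.rate,
            harmonic_amps=p.harmonic_amps,
            snr_db=p.snr_db,
            noise_exponent=p.noise_exponent,
            line_amp=p.line_amp,
            n_channels=n_ch,
            band=p.band,
            seed=seed * 100003 + k,
        )
        i0 = int(round((onset + delay_s) * p.rate))
        eeg[i0: i0 + n_epoch] += simulate_ssvep_epoch(trial_p)
        onsets.append((onset, float(f)))
    eeg_stream = TimedStream(
        name="eeg", channel_labels=labels, samples=eeg,
        nominal_rate=p.rate, timestamps=t,
    )
    markers = TimedStream(
        name="markers",
        channel_labels=["freq_hz"],
        samples=np.array([[f] for _, f in onsets]),
        nominal_rate=1.0 / slot,
        timestamps=np.array([o for o, _ in onsets]),
    )
    truth = {
        "onsets": onsets,
        "hardware_offset_ms": hardware_offset_ms,
        "ocular_delay_ms": ocular_delay_ms,
        "flicker_period_s": p.flicker_period,
        "snr_db": p.snr_db,
        "seed": seed,
    }
    rec = Recording(
        streams=[eeg_stream, markers],
        metadata={"session_id": f"synthetic-ssvep-seed{seed}", "synthetic": True},
    )
    return rec, truth


def simulate_ssvep_trial(p: SsvepSimParams, decoder=None):
    """Generate one epoch and classify it; returns an SsvepTrial.

    The trial's ``true_freq`` is the generator's stimulus frequency; the
    classification uses the supplied decoder or a default
    :class:`~vrsync.ssvep.SsvepDecoder`.
    """
    from .ssvep import SsvepDecoder

    decoder = decoder or SsvepDecoder()
    epoch = simulate_ssvep_epoch(p)
    return decoder.decode(epoch, p.rate, true_freq=p.freq)
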