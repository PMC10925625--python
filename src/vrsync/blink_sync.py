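"""Blink-based estimation of the offset between eye-tracker and EEG/EMG streams.

The eye tracker integrated in a VR headset and an EEG/EMG amplifier stamp
the same physical event — an eye blink — at different times: the tracker's
internal latency, its coarse 120 Hz device grid, and the transport path all
contribute a hardware offset plus jitter that middleware-level clock
synchronization cannot see. This module estimates that offset from paced
blinks: the blink appears as the onset of the ``both_blinking`` flag in the
eye stream and as a burst in a periocular EMG channel. Per blink, the
offset is the time from the eye-closure onset to the 90%-of-peak rising
crossing of the band-passed EMG burst; per session, blinks are aggregated
into a mean offset and a jitter (STD) after excluding distorted bursts and
3-sigma outliers.

Sign convention: positive offset means the eye-tracker event precedes the
EMG landmark (the tracker is "faster"); downstream correction delays the
eye-tracker timestamps by the offset to land them on the EEG clock.

The user-facing entry points follow the model/results pattern::

    model = BlinkOffsetModel(recording, config=BlinkSyncConfig())
    res = model.fit()
    print(res.summary())
    res.mean_offset_ms, res.std_ms
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .streams import (
    EyeChannels,
    Recording,
    StreamError,
    TimedStream,
    dejitter,
    downsample,
)


class BlinkSyncError(ValueError):
    """Raised when blink-based offset estimation cannot proceed."""


@dataclass
class BlinkSyncConfig:
    """Parameters of the blink-offset estimator.

    band_low, band_high : Hz
        Pass band of the zero-phase Butterworth applied to the EMG channel;
        the 0.75–5 Hz default isolates blink bursts from drift and EMG
        high-frequency content.
    filter_order : int
        Butterworth order (applied forward-backward, so the effective
        attenuation is doubled).
    peak_fraction : float
        The per-blink EMG landmark is the first rising crossing of
        ``peak_fraction × max`` at or before the burst maximum; 0.9 makes
        the landmark robust to differing burst slopes.
    closure_threshold : float
        Eye openness below this value counts as closed (device rule: 0.1).
    outlier_k : float
        Blinks farther than ``outlier_k × STD`` from the mean offset are
        excluded in a single pass.
    padding : int
        Samples of context taken on each side of an eye-closure onset when
        cutting per-blink windows; 125 at 250 Hz = 0.5 s, covering one full
        blink at 60 BPM pacing without overlapping neighbors.
    analysis_rate : Hz
        Common rate both streams are brought to before index arithmetic.
    distort_peak_fraction, distort_sep_ms, distort_amp_ratio :
        Distorted-burst rejection: a window is rejected when it holds two
        or more peaks each above ``distort_peak_fraction × max`` separated
        by more than ``distort_sep_ms``, or when its maximum is below
        ``distort_amp_ratio`` times the filtered channel's median absolute
        amplitude (no discernible burst).
    """

    band_low: float = 0.75
    band_high: float = 5.0
    filter_order: int = 3
    peak_fraction: float = 0.9
    closure_threshold: float = 0.1
    outlier_k: float = 3.0
    padding: int = 125
    analysis_rate: float = 250.0
    eye_device_rate: float = 120.0
    distort_peak_fraction: float = 0.7
    distort_sep_ms: float = 200.0
    distort_amp_ratio: float = 5.0
    emg_channel: str = "EMG"
    eye_stream: str = "eye"
    emg_stream: str = "emg"
    dejitter_method: str = "ols"

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.analysis_rate / 2):
            raise BlinkSyncError(
                f"band ({self.band_low}, {self.band_high}) Hz must sit inside "
                f"(0, {self.analysis_rate / 2}) Hz"
            )
        if not (0 < self.peak_fraction <= 1):
            raise BlinkSyncError("peak_fraction must be in (0, 1]")
        if not self.outlier_k > 0:
            raise BlinkSyncError("outlier_k must be > 0")


@dataclass
class BlinkEvent:
    """One blink's landmarks and validity.

    ``offset_ms = (emg_peak_index − eye_onset_index) × 1000 / analysis_rate``
    when both indices live on the same sampling grid; positive means the
    eye-tracker saw the blink first.
    """

    eye_onset_index: int
    emg_peak_index: int | None
    offset_ms: float | None
    valid: bool
    exclusion_reason: str | None = None  # distorted_emg | outlier | truncated


@dataclass
class OffsetEstimate:
    """Aggregated offset over one or more recordings."""

    mean_offset_ms: float
    std_ms: float
    n_used: int
    n_excluded: int
    per_recording: list[tuple[str, float, float, int]] = field(default_factory=list)
    events: list[BlinkEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-signal operations
# ---------------------------------------------------------------------------

def filter_emg(x: np.ndarray, rate: float, cfg: BlinkSyncConfig | None = None) -> np.ndarray:
    """Band-pass the EMG channel with a zero-phase Butterworth filter.

    Forward-backward application cancels the filter's phase response, so
    burst landmarks are not delayed — essential, since the delay being
    measured is itself of filter-transient magnitude.
    """
    cfg = cfg or BlinkSyncConfig()
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise BlinkSyncError("non-finite sample in EMG signal")
    min_len = 6 * cfg.filter_order + 1
    if x.size <= min_len:
        raise BlinkSyncError(
            f"EMG signal too short to filter: {x.size} samples, need > {min_len}"
        )
    sos = signal.butter(
        cfg.filter_order,
        (cfg.band_low, cfg.band_high),
        btype="bandpass",
        fs=rate,
        output="sos",
    )
    return signal.sosfiltfilt(sos, x)


def find_blink_onsets(both_blinking: np.ndarray) -> np.ndarray:
    """Indices of the first sample of each maximal run of 1s."""
    b = np.asarray(both_blinking, dtype=float).ravel()
    if not np.isin(b, (0.0, 1.0)).all():
        raise BlinkSyncError("both_blinking must be binary (0/1)")
    rising = np.flatnonzero(np.diff(np.concatenate(([0.0], b))) == 1.0)
    return rising


def closure_from_openness(openness: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Binary closure series: 1 where openness is strictly below *threshold*."""
    x = np.asarray(openness, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise BlinkSyncError("openness values must lie in [0, 1]")
    return (x < threshold).astype(float)


def emg_peak_index(window: np.ndarray, peak_fraction: float = 0.9) -> int:
    """Landmark index of a filtered EMG burst.

    The landmark is the earliest index at or before the window's absolute
    maximum where the signal first reaches ``peak_fraction × max`` — a
    rising-slope crossing, invariant to amplitude scaling and robust to
    plateaued peaks (ties resolve to the earliest maximum).
    """
    w = np.asarray(window, dtype=float).ravel()
    if w.size == 0 or np.ptp(w) == 0 or w.max() <= 0:
        raise BlinkSyncError("no EMG peak: window is constant or non-positive")
    imax = int(np.argmax(w))
    thresh = peak_fraction * w[imax]
    crossed = np.flatnonzero(w[: imax + 1] >= thresh)
    return int(crossed[0])


def single_blink_offset(
    eye_window: np.ndarray,
    emg_window: np.ndarray,
    cfg: BlinkSyncConfig | None = None,
    *,
    emg_prefiltered: bool = False,
    channel_median_abs: float | None = None,
) -> BlinkEvent:
    """Offset of a single blink from aligned eye / EMG windows.

    Both windows must cover the same clock interval at ``cfg.analysis_rate``
    (same start sample on the shared grid). The eye window is the binary
    ``both_blinking`` series; the EMG window is filtered here unless
    *emg_prefiltered* is set.
    """
    cfg = cfg or BlinkSyncConfig()
    eye_window = np.asarray(eye_window, dtype=float).ravel()
    onsets = find_blink_onsets(eye_window)
    if onsets.size == 0:
        raise BlinkSyncError("no closure found in eye window")
    eye_onset = int(onsets[0])
    emg = np.asarray(emg_window, dtype=float).ravel()
    if not emg_prefiltered:
        emg = filter_emg(emg, cfg.analysis_rate, cfg)
    if _is_distorted(emg, cfg, channel_median_abs):
        return BlinkEvent(eye_onset, None, None, False, "distorted_emg")
    try:
        peak = emg_peak_index(emg, cfg.peak_fraction)
    except BlinkSyncError:
        return BlinkEvent(eye_onset, None, None, False, "distorted_emg")
    offset_ms = (peak - eye_onset) * 1000.0 / cfg.analysis_rate
    return BlinkEvent(eye_onset, peak, offset_ms, True, None)


def _is_distorted(
    emg: np.ndarray, cfg: BlinkSyncConfig, channel_median_abs: float | None
) -> bool:
    """Distorted-burst rule: multiple comparable peaks, or no burst at all."""
    mx = emg.max()
    if mx <= 0:
        return True
    if channel_median_abs is not None and channel_median_abs > 0:
        if mx < cfg.distort_amp_ratio * channel_median_abs:
            return True
    sep = max(1, int(round(cfg.distort_sep_ms / 1000.0 * cfg.analysis_rate)))
    peaks, _ = signal.find_peaks(emg, height=cfg.distort_peak_fraction * mx)
    if peaks.size >= 2 and (peaks[-1] - peaks[0]) > sep:
        return True
    return False


def aggregate_offsets(
    events: Sequence[BlinkEvent],
    cfg: BlinkSyncConfig | None = None,
    recording_id: str = "recording",
) -> OffsetEstimate:
    """Mean offset and jitter over valid blinks, with one outlier pass.

    Mean and STD are computed over valid events; events deviating from the
    mean by more than ``outlier_k × STD`` are then excluded (single pass,
    not iterated) and the statistics recomputed.
    """
    cfg = cfg or BlinkSyncConfig()
    events = list(events)
    valid = [e for e in events if e.valid]
    if len(valid) < 2:
        raise BlinkSyncError(
            f"insufficient blinks: need >= 2 valid events, have {len(valid)}"
        )
    offs = np.array([e.offset_ms for e in valid])
    mean0, std0 = float(offs.mean()), float(offs.std(ddof=1))
    keep = np.abs(offs - mean0) <= cfg.outlier_k * std0
    for e, k in zip(valid, keep):
        if not k:
            e.valid = False
            e.exclusion_reason = "outlier"
    kept = offs[keep]
    if kept.size < 2:
        raise BlinkSyncError("insufficient blinks after outlier exclusion")
    mean = float(kept.mean())
    std = float(kept.std(ddof=1))
    n_used = int(kept.size)
    n_excluded = len(events) - n_used
    return OffsetEstimate(
        mean_offset_ms=mean,
        std_ms=std,
        n_used=n_used,
        n_excluded=n_excluded,
        per_recording=[(recording_id, mean, std, n_used)],
        events=events,
    )


# ---------------------------------------------------------------------------
# Whole-recording pipeline
# ---------------------------------------------------------------------------

def _blink_events(rec: Recording, cfg: BlinkSyncConfig) -> list[BlinkEvent]:
    """dejitter → resample → onset detection → windowing → per-blink offsets."""
    if cfg.eye_stream not in rec:
        raise BlinkSyncError(f"stage streams: recording lacks {cfg.eye_stream!r}")
    if cfg.emg_stream not in rec:
        raise BlinkSyncError(f"stage streams: recording lacks {cfg.emg_stream!r}")
    eye = dejitter(rec[cfg.eye_stream], cfg.dejitter_method)
    emg_s = dejitter(rec[cfg.emg_stream], cfg.dejitter_method)
    if emg_s.nominal_rate > cfg.analysis_rate:
        emg_s = downsample(emg_s, cfg.analysis_rate)
    if eye.nominal_rate > cfg.analysis_rate:
        eye = downsample(eye, cfg.analysis_rate)

    chans = EyeChannels.from_stream(eye)
    if "both_blinking" in eye.channel_labels:
        blink = chans.both_blinking
    else:
        # derive closure from the weaker eye's openness
        blink = closure_from_openness(
            np.minimum(chans.left_openness, chans.right_openness),
            cfg.closure_threshold,
        )
    onsets = find_blink_onsets(blink)
    if onsets.size == 0:
        raise BlinkSyncError("stage onsets: no closure found in recording")

    emg_raw = emg_s.channel(cfg.emg_channel)
    emg_filt = filter_emg(emg_raw, cfg.analysis_rate, cfg)
    med_abs = float(np.median(np.abs(emg_filt)))

    pad = cfg.padding
    dt = 1.0 / cfg.analysis_rate
    events: list[BlinkEvent] = []
    for onset in onsets:
        t_on = eye.timestamps[onset]
        lo_eye, hi_eye = onset - pad, onset + pad + 1
        # same clock interval in the EMG stream (grids may start apart)
        e_lo = int(np.searchsorted(emg_s.timestamps, t_on - pad * dt - dt / 2))
        e_hi = e_lo + (hi_eye - lo_eye)
        if lo_eye < 0 or hi_eye > eye.n_samples or e_lo < 0 or e_hi > emg_s.n_samples:
            events.append(BlinkEvent(int(onset), None, None, False, "truncated"))
            continue
        ev = single_blink_offset(
            blink[lo_eye:hi_eye],
            emg_filt[e_lo:e_hi],
            cfg,
            emg_prefiltered=True,
            channel_median_abs=med_abs,
        )
        if ev.valid:
            # express landmarks on the shared clock, not the window
            t_eye = eye.timestamps[lo_eye + ev.eye_onset_index]
            t_emg = emg_s.timestamps[e_lo + ev.emg_peak_index]
            ev = BlinkEvent(
                eye_onset_index=lo_eye + ev.eye_onset_index,
                emg_peak_index=e_lo + ev.emg_peak_index,
                offset_ms=float((t_emg - t_eye) * 1000.0),
                valid=True,
            )
        else:
            ev = replace(ev, eye_onset_index=lo_eye + ev.eye_onset_index)
        events.append(ev)
    return events


def estimate_offset(
    rec: Recording, cfg: BlinkSyncConfig | None = None, recording_id: str | None = None
) -> OffsetEstimate:
    """Run the full pipeline on one recording and aggregate its blinks."""
    cfg = cfg or BlinkSyncConfig()
    rid = recording_id or rec.metadata.get("session_id", "recording")
    events = _blink_events(rec, cfg)
    return aggregate_offsets(events, cfg, recording_id=rid)


# ---------------------------------------------------------------------------
# Trimming-strategy selection across recordings
# ---------------------------------------------------------------------------

TRIM_STRATEGIES = ("none", "head", "tail", "symmetric")


def _trim(events: list[BlinkEvent], m: int, strategy: str) -> list[BlinkEvent]:
    n = len(events)
    if m >= n:
        return events
    if strategy == "none":
        return events
    if strategy == "head":
        return events[n - m:]
    if strategy == "tail":
        return events[:m]
    if strategy == "symmetric":
        cut = n - m
        lo = cut // 2
        return events[lo: lo + m]
    raise BlinkSyncError(f"unknown trimming strategy {strategy!r}")


def select_trimming(
    recordings: Sequence[Recording],
    strategies: Sequence[str] = TRIM_STRATEGIES,
    cfg: BlinkSyncConfig | None = None,
) -> tuple[str, OffsetEstimate]:
    """Pick the blink-trimming strategy minimizing pooled STD.

    Recordings of a session often hold different numbers of blinks; each
    candidate strategy trims every recording's blink list to the shortest
    common length (from the head, the tail, or symmetrically — or not at
    all) before pooling. The strategy with minimal pooled STD wins; ties go
    to the first listed.
    """
    cfg = cfg or BlinkSyncConfig()
    if not recordings:
        raise BlinkSyncError("no recordings given")
    if not strategies:
        raise BlinkSyncError("empty strategy list")
    all_events = [_blink_events(rec, cfg) for rec in recordings]
    m = min(len(ev) for ev in all_events)
    best: tuple[str, OffsetEstimate] | None = None
    errors = []
    for strat in strategies:
        try:
            import copy

            trimmed = [
                _trim(copy.deepcopy(ev), m, strat) for ev in all_events
            ]
            pooled: list[BlinkEvent] = [e for ev in trimmed for e in ev]
            est = aggregate_offsets(pooled, cfg, recording_id="pooled")
            est.per_recording = [
                (
                    f"recording_{i}",
                    float(np.mean(offs)) if offs else math.nan,
                    float(np.std(offs, ddof=1)) if len(offs) > 1 else math.nan,
                    len(offs),
                )
                for i, ev in enumerate(trimmed)
                for offs in [[e.offset_ms for e in ev if e.valid]]
            ]
        except BlinkSyncError as exc:
            errors.append(f"{strat}: {exc}")
            continue
        if best is None or est.std_ms < best[1].std_ms:
            best = (strat, est)
    if best is None:
        raise BlinkSyncError(
            "all trimming strategies failed: " + "; ".join(errors)
        )
    return best


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class BlinkOffsetModel:
    """Hardware-offset model for one or more blink recordings.

    Parameters
    ----------
    data : Recording or sequence of Recording
        Recordings holding an EMG stream and an eye-tracking stream on one
        shared clock.
    config : BlinkSyncConfig, optional
    strategies : sequence of str, optional
        Trimming strategies evaluated when several recordings are given;
        ignored for a single recording.
    """

    def __init__(
        self,
        data: Recording | Sequence[Recording],
        config: BlinkSyncConfig | None = None,
        strategies: Sequence[str] = TRIM_STRATEGIES,
    ) -> None:
        self.recordings = [data] if isinstance(data, Recording) else list(data)
        if not self.recordings:
            raise BlinkSyncError("no recordings given")
        self.config = config or BlinkSyncConfig()
        self.strategies = tuple(strategies)

    def fit(self) -> "BlinkOffsetResults":
        if len(self.recordings) == 1:
            est = estimate_offset(self.recordings[0], self.config)
            strategy = "none"
        else:
            strategy, est = select_trimming(
                self.recordings, self.strategies, self.config
            )
        return BlinkOffsetResults(self, est, strategy)


class BlinkOffsetResults:
    """Fitted offset, jitter, and per-blink diagnostics."""

    def __init__(
        self, model: BlinkOffsetModel, estimate: OffsetEstimate, strategy: str
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.strategy = strategy

    @property
    def mean_offset_ms(self) -> float:
        return self.estimate.mean_offset_ms

    @property
    def std_ms(self) -> float:
        """Jitter: STD of per-blink offsets after exclusions."""
        return self.estimate.std_ms

    @property
    def n_used(self) -> int:
        return self.estimate.n_used

    @property
    def n_excluded(self) -> int:
        return self.estimate.n_excluded

    @property
    def sem_ms(self) -> float:
        """Standard error of the mean offset."""
        return self.std_ms / math.sqrt(self.n_used)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for the mean offset."""
        from scipy import stats as _st

        z = _st.norm.ppf(1 - alpha / 2)
        return (self.mean_offset_ms - z * self.sem_ms, self.mean_offset_ms + z * self.sem_ms)

    def to_dict(self) -> dict:
        return {
            "mean_offset_ms": self.mean_offset_ms,
            "std_ms": self.std_ms,
            "sem_ms": self.sem_ms,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "trimming_strategy": self.strategy,
            "per_recording": [
                {"id": rid, "mean_ms": m, "std_ms": s, "n": n}
                for rid, m, s, n in self.estimate.per_recording
            ],
            "exclusions": [
                {"eye_onset_index": e.eye_onset_index, "reason": e.exclusion_reason}
                for e in self.estimate.events
                if not e.valid
            ],
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Blink-based stream offset estimate",
            "==================================",
            f"mean offset        {self.mean_offset_ms:10.2f} ms",
            f"jitter (STD)       {self.std_ms:10.2f} ms",
            f"SEM                {self.sem_ms:10.2f} ms",
            f"95% CI             [{lo:.2f}, {hi:.2f}] ms",
            f"blinks used        {self.n_used:10d}",
            f"blinks excluded    {self.n_excluded:10d}",
            f"trimming strategy  {self.strategy:>10s}",
            "",
            "Positive offset: eye-tracker event precedes the EMG landmark;",
            "delay eye-tracker timestamps by the offset to align streams.",
        ]
        excl = [e for e in self.estimate.events if not e.valid]
        if excl:
            lines.append("")
            lines.append("excluded blinks:")
            for e in excl:
                lines.append(
                    f"  onset index {e.eye_onset_index}: {e.exclusion_reason}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BlinkOffsetResults mean={self.mean_offset_ms:.2f} ms "
            f"std={self.std_ms:.2f} ms n={self.n_used}>"
        )
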