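"""SSVEP speller backend: preprocessing, CCA classification, accuracy and ITR.

A flickering stimulus at frequency f evokes a steady-state visually evoked
potential (SSVEP) — occipito-parietal EEG power at f and its harmonics.
The speller flashes a six-letter cluster at one of six frequencies
(4, 5, 5.5, 6, 7, 7.4 Hz) and decodes which letter was attended by
comparing the EEG epoch against sinusoidal reference sets at each candidate
frequency with canonical correlation analysis (CCA): the frequency whose
references correlate best wins. Epochs are aligned to the moment the
flicker reaches the visual cortex, i.e. flicker onset shifted by the
measured hardware offset between the stimulus/eye-tracker clock and the
EEG clock plus a fixed ~100 ms ocular conduction delay.

Session quality is scored as classification accuracy and the Wolpaw
information transfer rate (ITR) in bits per minute.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, signal

from .streams import Recording, StreamError


class SsvepError(ValueError):
    """Raised for invalid SSVEP inputs or degenerate numerics."""


#: Stimulus frequencies used by the six-letter clusters, Hz.
DEFAULT_FREQUENCIES = (4.0, 5.0, 5.5, 6.0, 7.0, 7.4)

#: Occipito-parietal electrodes carrying the SSVEP response.
DEFAULT_CHANNELS = ("O1", "Oz", "O2", "P3", "P7", "Pz", "P8", "P4")


@dataclass
class StimulusSet:
    """The candidate flicker frequencies and their harmonic expansion."""

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    n_harmonics: int = 2
    flicker_period: float = 4.0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if any(f <= 0 for f in freqs):
            raise SsvepError("stimulus frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise SsvepError("stimulus frequencies must be distinct")
        if self.n_harmonics < 1:
            raise SsvepError("n_harmonics must be >= 1")
        self.frequencies = tuple(sorted(freqs))


@dataclass
class SsvepConfig:
    """Preprocessing and alignment parameters.

    The notch removes mains interference; the band-pass brackets the
    stimulus fundamentals and their modelled harmonics. ``ocular_delay_ms``
    is the retina-to-cortex conduction time added on top of the measured
    ``hardware_offset_ms`` when converting a flicker onset on the
    stimulus clock into an EEG epoch start.
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    band: tuple[float, float] = (1.0, 15.0)
    filter_order: int = 3
    ocular_delay_ms: float = 100.0
    hardware_offset_ms: float = 0.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    pad_s: float = 0.5
    cca_ridge: float = 1e-8
    itr_n_targets: int = 30
    eeg_stream: str = "eeg"

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise SsvepError(f"band {self.band} must satisfy 0 < low < high")
        if self.ocular_delay_ms < 0:
            raise SsvepError("ocular delay must be >= 0")

    def validate_against(self, stim: StimulusSet, rate: float) -> None:
        lo, hi = self.band
        if hi >= rate / 2:
            raise SsvepError(f"band edge {hi} Hz at or above Nyquist {rate / 2} Hz")
        top = max(stim.frequencies) * stim.n_harmonics
        if top > hi:
            warnings.warn(
                f"highest modelled harmonic {top} Hz exceeds the band-pass "
                f"edge {hi} Hz and will be attenuated",
                stacklevel=2,
            )


@dataclass
class SsvepTrial:
    """One flicker period's epoch and its classification."""

    epoch: np.ndarray
    rate: float
    true_freq: float | None = None
    predicted_freq: float | None = None
    correlations: dict[float, float] = field(default_factory=dict)


@dataclass
class SessionScore:
    """Accuracy and information transfer rate of a test session."""

    accuracy: float
    itr_bpm: float
    n_trials: int
    flicker_period: float


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_epoch(
    epoch: np.ndarray, rate: float, cfg: SsvepConfig | None = None
) -> np.ndarray:
    """Notch + zero-phase band-pass, per channel, length-preserving.

    Each channel is extended with reflected padding, notch-filtered at the
    mains frequency, band-pass filtered forward-backward, then the padding
    is removed to restore the original length.
    """
    cfg = cfg or SsvepConfig()
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if x.shape[0] == 1 and np.asarray(epoch).ndim == 1:
        x = x.T
    pad = int(round(cfg.pad_s * rate))
    if x.shape[0] <= pad or x.shape[0] <= 9 * cfg.filter_order:
        raise SsvepError(
            f"epoch of {x.shape[0]} samples is shorter than the {pad}-sample padding"
        )
    padded = np.concatenate(
        [x[pad:0:-1], x, x[-2: -pad - 2: -1]], axis=0
    )
    b_n, a_n = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rate)
    out = signal.filtfilt(b_n, a_n, padded, axis=0)
    sos = signal.butter(
        cfg.filter_order, cfg.band, btype="bandpass", fs=rate, output="sos"
    )
    out = signal.sosfiltfilt(sos, out, axis=0)
    out = out[pad: pad + x.shape[0]]
    return out if np.asarray(epoch).ndim > 1 else out.ravel()


# ---------------------------------------------------------------------------
# References and CCA
# ---------------------------------------------------------------------------

def make_reference(
    freq: float, rate: float, n_samples: int, n_harmonics: int = 2
) -> np.ndarray:
    """Sin/cos reference matrix at *freq* and its harmonics.

    Columns are sin(2π h f t) and cos(2π h f t) for h = 1..n_harmonics,
    with t = 0 at flicker onset, shape (n_samples, 2 n_harmonics).
    """
    if freq * n_harmonics >= rate / 2:
        raise SsvepError(
            f"harmonic {freq * n_harmonics} Hz at or above Nyquist {rate / 2} Hz"
        )
    if n_samples < rate / freq:
        raise SsvepError(
            f"epoch of {n_samples} samples covers less than one cycle of {freq} Hz"
        )
    t = np.arange(n_samples) / rate
    cols = []
    for h in range(1, n_harmonics + 1):
        w = 2 * np.pi * h * freq * t
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def cca_max_corr(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> float:
    """Largest canonical correlation between column spaces of X and Y.

    Columns are centered internally; the correlation is the largest
    singular value of the whitened cross-covariance
    C_xx^{-1/2} C_xy C_yy^{-1/2}, with a trace-normalized ridge added to
    the auto-covariance diagonals for stability on short epochs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise SsvepError(
            f"row-count mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}"
        )
    n = X.shape[0]
    if n < max(X.shape[1], Y.shape[1]) + 2:
        raise SsvepError("too few rows for the number of columns")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    Cxx += ridge * (np.trace(Cxx) / Cxx.shape[0] + 1e-300) * np.eye(Cxx.shape[0])
    Cyy += ridge * (np.trace(Cyy) / Cyy.shape[0] + 1e-300) * np.eye(Cyy.shape[0])
    try:
        Lx = linalg.cholesky(Cxx, lower=True)
        Ly = linalg.cholesky(Cyy, lower=True)
    except linalg.LinAlgError:
        raise SsvepError("degenerate covariance: not positive definite") from None
    M = linalg.solve_triangular(Lx, Cxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    s = linalg.svdvals(M)
    if not np.isfinite(s).all():
        raise SsvepError("degenerate covariance: non-finite singular values")
    return float(np.clip(s[0], 0.0, 1.0))


def classify_epoch(
    epoch: np.ndarray,
    rate: float,
    stim: StimulusSet | None = None,
    cfg: SsvepConfig | None = None,
    true_freq: float | None = None,
) -> SsvepTrial:
    """Classify a preprocessed epoch by maximal canonical correlation.

    Frequencies are scanned in ascending order and the argmax taken, so a
    tie deterministically resolves to the lower frequency.
    """
    stim = stim or StimulusSet()
    cfg = cfg or SsvepConfig()
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if x.shape[0] == 1 and np.asarray(epoch).ndim == 1:
        x = x.T
    correlations: dict[float, float] = {}
    best_f, best_rho = None, -np.inf
    for f in stim.frequencies:  # ascending (sorted in __post_init__)
        ref = make_reference(f, rate, x.shape[0], stim.n_harmonics)
        rho = cca_max_corr(x, ref, ridge=cfg.cca_ridge)
        correlations[f] = rho
        if rho > best_rho:
            best_f, best_rho = f, rho
    return SsvepTrial(
        epoch=x,
        rate=rate,
        true_freq=true_freq,
        predicted_freq=best_f,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

def extract_epoch(
    rec: Recording,
    flicker_onset: float,
    period: float,
    cfg: SsvepConfig | None = None,
    rate: float | None = None,
) -> np.ndarray:
    """Cut the EEG epoch for one flicker period, alignment-corrected.

    The epoch starts at ``flicker_onset + hardware_offset_ms +
    ocular_delay_ms`` — the flicker's arrival at the visual cortex on the
    EEG clock — and spans ``round(period × rate)`` samples of the
    configured occipito-parietal channels, half-open window.
    """
    cfg = cfg or SsvepConfig()
    try:
        eeg = rec[cfg.eeg_stream]
    except KeyError as exc:
        raise SsvepError(str(exc)) from None
    rate = rate or eeg.nominal_rate
    start = flicker_onset + (cfg.hardware_offset_ms + cfg.ocular_delay_ms) / 1000.0
    n = int(round(period * rate))
    i0 = int(np.searchsorted(eeg.timestamps, start - 0.5 / rate))
    if i0 + n > eeg.n_samples:
        raise SsvepError(
            f"epoch out of bounds: needs samples [{i0}, {i0 + n}) of "
            f"{eeg.n_samples}"
        )
    try:
        return eeg.select(cfg.channels)[i0: i0 + n]
    except StreamError as exc:
        raise SsvepError(str(exc)) from None


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def itr_bpm(P: float, N: int, T: float) -> float:
    """Wolpaw information transfer rate in bits per minute.

    Bits per selection B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1));
    ITR = 60 B / T for selection time T seconds. The P → 1 limit is
    log2 N; at chance level P = 1/N the rate is exactly zero.
    """
    if N < 2:
        raise SsvepError("need at least 2 selectable targets")
    if T <= 0:
        raise SsvepError("selection time must be positive")
    if P > 1:
        raise SsvepError("accuracy cannot exceed 1")
    chance = 1.0 / N
    if P < chance - 1e-12:
        raise SsvepError(
            f"accuracy {P:.3f} below chance 1/{N}; ITR undefined here"
        )
    if P >= 1.0:
        bits = math.log2(N)
    elif abs(P - chance) <= 1e-12:
        return 0.0
    else:
        bits = (
            math.log2(N)
            + P * math.log2(P)
            + (1 - P) * math.log2((1 - P) / (N - 1))
        )
    return max(0.0, bits) * 60.0 / T


def score_session(
    trials: Sequence[SsvepTrial],
    stim: StimulusSet | None = None,
    selection_time: float | None = None,
    n_targets: int | None = None,
) -> SessionScore:
    """Accuracy and ITR over labelled trials.

    ``selection_time`` defaults to the stimulus set's flicker period and
    ``n_targets`` to 30 (a full keyboard reachable through gaze
    pre-selection); both are explicit knobs because ITR depends on how the
    selection time and target count are accounted.
    """
    stim = stim or StimulusSet()
    trials = list(trials)
    if not trials:
        raise SsvepError("no trials to score")
    if any(t.true_freq is None for t in trials):
        raise SsvepError("every trial needs a known true frequency")
    T = selection_time if selection_time is not None else stim.flicker_period
    N = n_targets if n_targets is not None else SsvepConfig().itr_n_targets
    correct = sum(1 for t in trials if t.predicted_freq == t.true_freq)
    acc = correct / len(trials)
    itr = itr_bpm(max(acc, 1.0 / N), N, T)
    return SessionScore(
        accuracy=acc, itr_bpm=itr, n_trials=len(trials), flicker_period=T
    )


class SsvepDecoder:
    """Convenience front-end bundling stimulus set + config.

    Not a trained model — CCA against fixed sinusoidal references needs no
    calibration data, which is precisely why the speller uses it.
    """

    def __init__(
        self, stim: StimulusSet | None = None, cfg: SsvepConfig | None = None
    ) -> None:
        self.stim = stim or StimulusSet()
        self.cfg = cfg or SsvepConfig()

    def decode(
        self, epoch: np.ndarray, rate: float, true_freq: float | None = None
    ) -> SsvepTrial:
        """Preprocess and classify one raw epoch."""
        self.cfg.validate_against(self.stim, rate)
        clean = preprocess_epoch(epoch, rate, self.cfg)
        return classify_epoch(clean, rate, self.stim, self.cfg, true_freq)

    def decode_recording(
        self,
        rec: Recording,
        onsets: Sequence[tuple[float, float]],
        period: float | None = None,
    ) -> list[SsvepTrial]:
        """Cut, preprocess and classify one epoch per (onset_s, true_freq)."""
        period = period or self.stim.flicker_period
        trials = []
        for onset, true_f in onsets:
            raw = extract_epoch(rec, onset, period, self.cfg)
            trials.append(self.decode(raw, rec[self.cfg.eeg_stream].nominal_rate, true_f))
        return trials

    def score(
        self, trials: Sequence[SsvepTrial], selection_time: float | None = None
    ) -> SessionScore:
        return score_session(trials, self.stim, selection_time)
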