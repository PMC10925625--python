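"""Timestamped multichannel streams: data model, dejittering, resampling, I/O.

A recording session produces several concurrently sampled streams — an
EEG/EMG stream from the amplifier and an eye-tracking stream from the VR
headset — each carrying its own per-sample timestamps on a shared clock.
Transport middleware stamps samples on arrival, so raw timestamps are
irregular ("jittery") even though the underlying hardware clocks are
regular; before any cross-stream timing analysis the timestamps are
regularized onto a fitted linear clock and the EEG stream is decimated from
its acquisition rate (500 Hz) to the common analysis rate (250 Hz).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal, stats


class StreamError(ValueError):
    """Raised for malformed or inconsistent stream data."""


@dataclass
class TimedStream:
    """One modality's samples with channel labels, nominal rate, timestamps.

    Parameters
    ----------
    name : str
        Stream label, unique within a :class:`Recording`.
    channel_labels : list of str
        One label per column of ``samples``.
    samples : ndarray, shape (n_samples, n_channels)
    nominal_rate : float
        Advertised sampling rate in Hz; must be positive.
    timestamps : ndarray, shape (n_samples,)
        Seconds on the session's shared clock.
    """

    name: str
    channel_labels: list[str]
    samples: np.ndarray
    nominal_rate: float
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1 and (
            len(self.channel_labels) == 1
        ):
            self.samples = self.samples.T
        self.timestamps = np.asarray(self.timestamps, dtype=float).ravel()
        if self.samples.shape[0] != self.timestamps.shape[0]:
            raise StreamError(
                f"stream {self.name!r}: {self.samples.shape[0]} sample rows "
                f"but {self.timestamps.shape[0]} timestamps"
            )
        if self.samples.shape[1] != len(self.channel_labels):
            raise StreamError(
                f"stream {self.name!r}: {self.samples.shape[1]} columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.nominal_rate > 0:
            raise StreamError(f"stream {self.name!r}: nominal_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples as a 1-D array."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise StreamError(
                f"stream {self.name!r} has no channel {label!r}; "
                f"available: {self.channel_labels}"
            ) from None
        return self.samples[:, idx]

    def select(self, labels: Sequence[str]) -> np.ndarray:
        """Return the given channels as an (n_samples, len(labels)) matrix."""
        return np.column_stack([self.channel(lab) for lab in labels])

    def slice_time(self, start: float, end: float) -> "TimedStream":
        """Samples with timestamps in the half-open window [start, end)."""
        lo = int(np.searchsorted(self.timestamps, start, side="left"))
        hi = int(np.searchsorted(self.timestamps, end, side="left"))
        return TimedStream(
            name=self.name,
            channel_labels=list(self.channel_labels),
            samples=self.samples[lo:hi],
            nominal_rate=self.nominal_rate,
            timestamps=self.timestamps[lo:hi],
        )


#: Channel labels the eye-tracking stream is expected to carry.
EYE_CHANNELS = [
    "left_closed",
    "right_closed",
    "both_blinking",
    "left_openness",
    "right_openness",
]


@dataclass
class EyeChannels:
    """The eye tracker's five channels of interest.

    Three binary channels flag closure of the left eye, the right eye, and
    both eyes simultaneously; two continuous channels give eyelid openness
    in [0, 1] (1 = fully open). The device reports an eye as closed when
    openness falls below 0.1.
    """

    left_closed: np.ndarray
    right_closed: np.ndarray
    both_blinking: np.ndarray
    left_openness: np.ndarray
    right_openness: np.ndarray

    def __post_init__(self) -> None:
        for lab in ("left_closed", "right_closed", "both_blinking"):
            arr = np.asarray(getattr(self, lab), dtype=float)
            if not np.isin(arr, (0.0, 1.0)).all():
                raise StreamError(f"binary channel {lab!r} has non-binary values")
            setattr(self, lab, arr)
        for lab in ("left_openness", "right_openness"):
            arr = np.asarray(getattr(self, lab), dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise StreamError(f"openness channel {lab!r} outside [0, 1]")
            setattr(self, lab, arr)

    @classmethod
    def from_stream(cls, stream: TimedStream) -> "EyeChannels":
        missing = [c for c in EYE_CHANNELS if c not in stream.channel_labels]
        have_binary = "both_blinking" in stream.channel_labels
        have_open = all(
            c in stream.channel_labels for c in ("left_openness", "right_openness")
        )
        if missing and not (have_binary or have_open):
            raise StreamError(
                f"stream {stream.name!r} missing eye channels: {missing}"
            )

        def get(lab: str, fallback: np.ndarray) -> np.ndarray:
            if lab in stream.channel_labels:
                return stream.channel(lab)
            return fallback

        n = stream.n_samples
        zeros = np.zeros(n)
        ones = np.ones(n)
        return cls(
            left_closed=get("left_closed", zeros),
            right_closed=get("right_closed", zeros),
            both_blinking=get("both_blinking", zeros),
            left_openness=get("left_openness", ones),
            right_openness=get("right_openness", ones),
        )


@dataclass
class Recording:
    """A session's streams on one shared clock, plus free-form metadata."""

    streams: list[TimedStream]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.streams:
            raise StreamError("recording has no streams")
        names = [s.name for s in self.streams]
        if len(set(names)) != len(names):
            raise StreamError(f"duplicate stream names: {names}")
        for s in self.streams:
            if s.n_samples == 0:
                raise StreamError(f"stream {s.name!r} is empty")

    def __getitem__(self, name: str) -> TimedStream:
        for s in self.streams:
            if s.name == name:
                return s
        raise KeyError(
            f"no stream named {name!r}; available: {[s.name for s in self.streams]}"
        )

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.streams)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.streams]


# ---------------------------------------------------------------------------
# Dejittering
# ---------------------------------------------------------------------------

def dejitter_timestamps(
    ts: np.ndarray, method: str = "ols"
) -> np.ndarray:
    """Regularize irregular per-sample timestamps onto a fitted linear clock.

    The underlying hardware clock is regular; transport stamps samples on
    arrival, adding jitter. A line is fitted to timestamp vs. sample index
    and the fitted values replace the raw stamps.

    Parameters
    ----------
    ts : array-like
        Raw timestamps, seconds.
    method : {"ols", "theil-sen"}
        Line estimator: ordinary least squares (default) or the robust
        Theil–Sen median-of-slopes estimator.

    Returns
    -------
    ndarray
        Fitted timestamps, strictly increasing. For OLS the mean residual
        (output − input) is zero by construction.
    """
    ts = np.asarray(ts, dtype=float).ravel()
    if ts.size < 2:
        raise StreamError("stream too short: need at least 2 samples to dejitter")
    idx = np.arange(ts.size, dtype=float)
    if method == "ols":
        slope, intercept = np.polyfit(idx, ts, 1)
    elif method in ("theil-sen", "theilsen"):
        slope, intercept, _, _ = stats.theilslopes(ts, idx)
    else:
        raise ValueError(f"unknown dejitter method {method!r}")
    if slope <= 0:
        raise StreamError("non-monotone clock: fitted slope is not positive")
    return intercept + slope * idx


def dejitter(stream: TimedStream, method: str = "ols") -> TimedStream:
    """Return a copy of *stream* with dejittered timestamps."""
    return TimedStream(
        name=stream.name,
        channel_labels=list(stream.channel_labels),
        samples=stream.samples,
        nominal_rate=stream.nominal_rate,
        timestamps=dejitter_timestamps(stream.timestamps, method=method),
    )


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

#: Anti-alias low-pass corner as a fraction of the target rate. Kept below
#: the target Nyquist (0.5) so aliased energy is strongly attenuated while
#: the analysis band passes untouched.
ANTIALIAS_CUTOFF_FRACTION = 0.45
ANTIALIAS_ORDER = 8


def downsample(stream: TimedStream, target_rate: float) -> TimedStream:
    """Decimate *stream* to *target_rate* with a zero-phase anti-alias filter.

    The factor ``nominal_rate / target_rate`` must be an integer. A
    forward-backward Butterworth low-pass (order 8, corner at 0.45 × target
    rate) precedes decimation; the zero-phase application adds no group
    delay, so decimation cannot bias downstream latency measurements.
    """
    if target_rate >= stream.nominal_rate:
        raise StreamError(
            f"target rate {target_rate} Hz must be below stream rate "
            f"{stream.nominal_rate} Hz"
        )
    factor_f = stream.nominal_rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise StreamError(
            f"non-integer decimation: {stream.nominal_rate} Hz / {target_rate} Hz"
        )
    sos = signal.butter(
        ANTIALIAS_ORDER,
        ANTIALIAS_CUTOFF_FRACTION * target_rate,
        btype="low",
        fs=stream.nominal_rate,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, stream.samples, axis=0)
    return TimedStream(
        name=stream.name,
        channel_labels=list(stream.channel_labels),
        samples=filtered[::factor],
        nominal_rate=target_rate,
        timestamps=stream.timestamps[::factor],
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
# CSV dialect: one header row, first column ``timestamp_s``, remaining
# columns are channel labels; UTF-8, "." decimal separator. A multi-stream
# recording is a directory of per-stream CSVs plus ``manifest.json`` holding
# stream names, nominal rates and session metadata. XDF reading is
# available when the optional ``pyxdf`` package is installed.

MANIFEST_NAME = "manifest.json"
_TIME_COL = "timestamp_s"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() == ".xdf":
        return "xdf"
    return "csv"


def _write_stream_csv(stream: TimedStream, path: Path) -> None:
    header = ",".join([_TIME_COL] + list(stream.channel_labels))
    data = np.column_stack([stream.timestamps, stream.samples])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")


def _read_stream_csv(path: Path, name: str, rate: float | None) -> TimedStream:
    import pandas as pd

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message carries the path
        raise StreamError(f"cannot parse {path}: {exc}") from exc
    if _TIME_COL not in df.columns:
        raise StreamError(f"stream without timestamps: {path} lacks '{_TIME_COL}'")
    ts = df[_TIME_COL].to_numpy(dtype=float)
    labels = [c for c in df.columns if c != _TIME_COL]
    if not labels:
        raise StreamError(f"{path}: no data channels besides '{_TIME_COL}'")
    if rate is None:
        if ts.size < 2:
            raise StreamError(f"{path}: cannot infer rate from < 2 samples")
        rate = 1.0 / float(np.median(np.diff(ts)))
    return TimedStream(
        name=name,
        channel_labels=labels,
        samples=df[labels].to_numpy(dtype=float),
        nominal_rate=rate,
        timestamps=ts,
    )


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write *rec* to disk. CSV only: a directory with one CSV per stream
    and a JSON manifest with names, rates, and metadata."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt != "csv":
        raise StreamError(f"writing format {fmt!r} is not supported; use 'csv'")
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"metadata": rec.metadata, "streams": []}
    for stream in rec.streams:
        fname = f"{stream.name}.csv"
        _write_stream_csv(stream, path / fname)
        manifest["streams"].append(
            {"name": stream.name, "nominal_rate": stream.nominal_rate, "file": fname}
        )
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from a CSV directory, a single CSV file, or XDF.

    A directory must contain ``manifest.json``; a bare CSV file becomes a
    single-stream recording named after the file; XDF needs ``pyxdf``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "xdf":
        return _read_xdf(path)
    if path.is_dir():
        mpath = path / MANIFEST_NAME
        if not mpath.exists():
            raise StreamError(f"cannot parse {path}: no {MANIFEST_NAME}")
        manifest = json.loads(mpath.read_text())
        streams = [
            _read_stream_csv(path / entry["file"], entry["name"], entry.get("nominal_rate"))
            for entry in manifest["streams"]
        ]
        return Recording(streams=streams, metadata=manifest.get("metadata", {}))
    stream = _read_stream_csv(path, path.stem, None)
    return Recording(streams=[stream])


def _read_xdf(path: Path) -> Recording:
    try:
        import pyxdf
    except ImportError:
        raise StreamError(
            "XDF support requires the optional 'pyxdf' package "
            "(pip install vrsync[xdf]); CSV recordings need no extras"
        ) from None
    raw_streams, header = pyxdf.load_xdf(str(path))
    streams = []
    for raw in raw_streams:
        info = raw["info"]
        name = info["name"][0]
        ts = np.asarray(raw["time_stamps"], dtype=float)
        if ts.size == 0:
            raise StreamError(f"stream without timestamps: {name!r} in {path}")
        rate = float(info["nominal_srate"][0])
        n_ch = int(info["channel_count"][0])
        try:
            chans = info["desc"][0]["channels"][0]["channel"]
            labels = [c["label"][0] for c in chans]
        except (TypeError, KeyError, IndexError):
            labels = [f"ch{i}" for i in range(n_ch)]
        streams.append(
            TimedStream(
                name=name,
                channel_labels=labels,
                samples=np.asarray(raw["time_series"], dtype=float),
                nominal_rate=rate if rate > 0 else 1.0 / np.median(np.diff(ts)),
                timestamps=ts,
            )
        )
    return Recording(streams=streams, metadata={"xdf_header": str(header)})


# ---------------------------------------------------------------------------
# Chunked replay
# ---------------------------------------------------------------------------

def replay_chunks(rec: Recording, chunk: float) -> Iterator[Recording]:
    """Yield the recording in consecutive *chunk*-second windows.

    Emulates online arrival of stream data. Chunks are aligned on the shared
    clock and concatenate back to the original recording; a stream may
    contribute zero samples to a window (it is then omitted from that chunk
    only if *all* streams are empty there — empty chunks are skipped).
    """
    if not chunk > 0:
        raise StreamError(f"chunk duration must be > 0, got {chunk}")
    t0 = min(float(s.timestamps[0]) for s in rec.streams)
    t1 = max(float(s.timestamps[-1]) for s in rec.streams)
    n_chunks = max(1, math.ceil((t1 - t0) / chunk))
    # half-open windows; the last window is extended to include t1 itself
    for i in range(n_chunks):
        lo = t0 + i * chunk
        hi = t0 + (i + 1) * chunk
        if i == n_chunks - 1:
            hi = np.nextafter(t1, np.inf)
        parts = [s.slice_time(lo, hi) for s in rec.streams]
        parts = [p for p in parts if p.n_samples > 0]
        if parts:
            yield Recording(streams=parts, metadata=dict(rec.metadata))
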