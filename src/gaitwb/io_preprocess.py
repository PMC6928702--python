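"""Reading and pre-processing of shank sensor recordings.

Turns raw tri-axial angular-velocity files into the calibrated, filtered
pitch angular-velocity signal per shank: projection onto the principal axis
of movement (medio-lateral alignment), zero-phase high-pass filtering to
remove drift, and detection of the initial lying posture on the
accelerometer norm for recording-start alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    DataError,
    DegenerateSignalError,
    FormatError,
    LyingOnsetNotFound,
    ParameterError,
)

__all__ = [
    "RawRecording",
    "PitchSignal",
    "DEFAULT_SCHEMA",
    "read_recording",
    "pca_align",
    "highpass_filter",
    "find_lying_onset",
]

#: Column mapping used when no schema is supplied; matches the CSV layout
#: written by :mod:`gaitwb.synthetic` and the CLI.
DEFAULT_SCHEMA = {
    "time": "time_s",
    "gyro": ["gyro_x", "gyro_y", "gyro_z"],
    "accel": ["accel_x", "accel_y", "accel_z"],
    "delimiter": ",",
}


@dataclass
class RawRecording:
    """One sensor's raw recording: tri-axial gyroscope, optional accelerometer.

    Angular velocity is in degrees per second, acceleration in g. ``t0`` is
    the time offset (seconds) of the first sample.
    """

    sensor_id: str
    side: str
    sampling_rate: float = 100.0
    gyro: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    accel: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3 or self.gyro.shape[0] == 0:
            raise DataError("gyro must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.gyro)):
            raise DataError("gyro contains non-finite values")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.shape != self.gyro.shape:
                raise DataError("accel and gyro must have equal shapes")

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class PitchSignal:
    """1-D angular velocity (deg/s) aligned with the medio-lateral axis."""

    side: str
    sampling_rate: float
    values: np.ndarray
    provenance: str = "raw-axis"  # {"raw-axis", "pca-aligned"}
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("PitchSignal values must be 1-D")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})


def read_recording(
    path,
    schema: dict | None = None,
    side: str = "left",
    sensor_id: str | None = None,
) -> RawRecording:
    """Read a CSV/TSV sensor file into a :class:`RawRecording`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema
        Column mapping: ``time`` (column name), ``gyro`` (3 column names),
        optionally ``accel`` (3 column names), ``delimiter`` and
        ``sampling_rate``. Missing keys fall back to :data:`DEFAULT_SCHEMA`.
    side, sensor_id
        Tags attached to the recording.

    Raises
    ------
    FormatError
        If a required column is absent.
    DataError
        If timestamps are non-monotone or jitter exceeds half a sample period.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, sep=sch.get("delimiter", ","))

    required = [sch["time"], *sch["gyro"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")

    t = df[sch["time"]].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("recording needs at least 2 samples to verify timing")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("timestamps are not strictly increasing")

    fs = sch.get("sampling_rate")
    if fs is None:
        fs = 1.0 / float(np.median(dt))
    period = 1.0 / fs
    if np.max(np.abs(dt - period)) >= 0.5 * period:
        raise DataError(
            f"timestamp jitter exceeds half a sample period at {fs:.6g} Hz"
        )

    gyro = df[list(sch["gyro"])].to_numpy(dtype=float)
    accel = None
    accel_cols = sch.get("accel")
    if accel_cols and all(c in df.columns for c in accel_cols):
        accel = df[list(accel_cols)].to_numpy(dtype=float)

    return RawRecording(
        sensor_id=sensor_id or str(path),
        side=side,
        sampling_rate=float(fs),
        gyro=gyro,
        accel=accel,
        t0=float(t[0]),
    )


def _dominant_tail_is_negative(x: np.ndarray, q: float = 0.995) -> bool:
    """Whether the largest-magnitude tail of ``x`` points downward.

    Compares the upper ``q`` quantile against the magnitude of the lower
    ``1 - q`` quantile. Midswing peaks are the largest-magnitude feature of
    the pitch signal, so the dominant tail must end up positive; counting
    local extrema instead is unreliable because the broad stance lobes
    contribute far more extrema than the narrow midswing peaks.
    """
    hi = float(np.quantile(x, q))
    lo = float(np.quantile(x, 1.0 - q))
    return abs(lo) > abs(hi)


def pca_align(
    recording: RawRecording,
    segment: tuple[float, float] | None = None,
) -> PitchSignal:
    """Project the tri-axial gyroscope onto its first principal axis.

    The principal axis is estimated on ``segment`` (a time window in seconds
    relative to the recording start, half-open) or on the whole recording.
    The sign is fixed so that the dominant (largest-magnitude) tail of the
    projection is positive, i.e. midswing peaks point up.

    Raises
    ------
    DegenerateSignalError
        If the estimation segment has (numerically) zero variance.
    """
    X = recording.gyro
    if segment is not None:
        i0 = max(0, int(np.floor(segment[0] * recording.sampling_rate)))
        i1 = min(X.shape[0], int(np.ceil(segment[1] * recording.sampling_rate)))
        seg = X[i0:i1]
        if seg.shape[0] < 2:
            raise ParameterError("PCA segment holds fewer than 2 samples")
    else:
        seg = X

    mean = seg.mean(axis=0)
    centered = seg - mean
    scale = float(np.max(np.abs(centered), initial=0.0))
    if scale == 0.0 or not np.isfinite(scale):
        raise DegenerateSignalError("zero-variance gyro segment: PCA undefined")

    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    values = (X - mean) @ axis

    if _dominant_tail_is_negative(values):
        values = -values

    return PitchSignal(
        side=recording.side,
        sampling_rate=recording.sampling_rate,
        values=values,
        provenance="pca-aligned",
        filtered=False,
    )


def highpass_filter(
    signal: PitchSignal,
    cutoff: float = 0.3,
    order: int = 4,
) -> PitchSignal:
    """Zero-phase high-pass Butterworth filter (drift / DC removal).

    Applied forward-backward (``sosfiltfilt``) so peak times are not shifted.
    Defaults (0.3 Hz, order 4) leave the gait band (0.5-3 Hz) untouched.
    """
    nyq = signal.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.butter(order, cutoff, btype="highpass", fs=signal.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.values)
    return replace(signal, values=filtered, filtered=True)


def find_lying_onset(
    accel: np.ndarray,
    sampling_rate: float,
    min_duration: float = 3.0,
    target_norm: float = 1.0,
    tolerance: float = 0.05,
) -> float:
    """Start time (s) of the first static ~1 g posture of ``min_duration``.

    The acceleration norm must stay within ``tolerance`` of ``target_norm``
    for at least ``min_duration`` seconds. Used to align the start of
    out-of-lab recordings on the initial lying posture.

    Raises
    ------
    LyingOnsetNotFound
        If no qualifying window exists.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3 or accel.shape[0] == 0:
        raise DataError("accel must be a non-empty (n, 3) array")
    norm = np.linalg.norm(accel, axis=1)
    ok = np.abs(norm - target_norm) <= tolerance

    min_len = max(1, int(round(min_duration * sampling_rate)))
    # run-length scan over the boolean mask
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return s / sampling_rate
    raise LyingOnsetNotFound(
        f"no window of >= {min_duration} s within {tolerance} g of {target_norm} g"
    )


def preprocess(
    recording: RawRecording,
    segment: tuple[float, float] | None = None,
    cutoff: float = 0.3,
    order: int = 4,
) -> PitchSignal:
    """PCA-align then high-pass filter a raw recording (convenience wrapper)."""
    aligned = pca_align(recording, segment=segment)
    return highpass_filter(aligned, cutoff=cutoff, order=order)
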