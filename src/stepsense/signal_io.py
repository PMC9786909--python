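"""Raw accelerometer I/O and derived signal series.

The raw CSV dialect is defined by this package (there is no community
standard for raw actigraphy CSV):

.. code-block:: text

    # sample_rate_hz=100.0
    # dynamic_range_g=8.0
    # device_label=wrist
    timestamp_iso8601,accel_x_g,accel_y_g,accel_z_g
    2022-01-03T00:00:00.000000,0.012345,-0.023456,0.998877
    ...

Metadata lines are optional; when ``sample_rate_hz`` is absent the rate is
inferred from the first two timestamps.  Acceleration values are written with
six decimal places of g, which round-trips every simulator output losslessly.
Timestamps are naive local time; no time-zone arithmetic is performed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import DataError, EmptyInputError, FormatError

__all__ = [
    "RawRecording",
    "MagnitudeSeries",
    "read_raw_csv",
    "write_raw_csv",
    "resample_linear",
    "vector_magnitude",
    "enmo_epochs",
    "apply_axis_correction",
]

RAW_HEADER = ("timestamp_iso8601", "accel_x_g", "accel_y_g", "accel_z_g")
#: decimal places of g preserved by write_raw_csv / read_raw_csv round-trips
RAW_DECIMALS = 6


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial acceleration trace in g.

    Sample timestamps are implicit: ``t_i = start_time + i / sample_rate_hz``.
    """

    start_time: datetime
    sample_rate_hz: float
    samples: np.ndarray  # shape (n, 3), g
    dynamic_range_g: float = 8.0
    device_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError(f"samples must have shape (n, 3), got {self.samples.shape}")
        if not self.sample_rate_hz > 0:
            raise DataError("sample_rate_hz must be positive")
        if not self.dynamic_range_g > 0:
            raise DataError("dynamic_range_g must be positive")
        if self.samples.size and np.abs(self.samples).max() > self.dynamic_range_g + 1e-9:
            raise DataError(
                f"|acceleration| exceeds dynamic range ±{self.dynamic_range_g} g"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Span covered by the samples (n / rate)."""
        return self.n_samples / self.sample_rate_hz

    def times(self) -> pd.DatetimeIndex:
        offsets = np.arange(self.n_samples) / self.sample_rate_hz
        return pd.Timestamp(self.start_time) + pd.to_timedelta(offsets, unit="s")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.start_time == other.start_time
            and self.sample_rate_hz == other.sample_rate_hz
            and self.dynamic_range_g == other.dynamic_range_g
            and self.device_label == other.device_label
            and self.samples.shape == other.samples.shape
            and bool(np.array_equal(self.samples, other.samples))
        )


@dataclass
class MagnitudeSeries:
    """Per-sample Euclidean norm of a tri-axial recording (g, gravity included)."""

    start_time: datetime
    sample_rate_hz: float
    values_g: np.ndarray

    def __post_init__(self) -> None:
        self.values_g = np.asarray(self.values_g, dtype=float)
        if self.values_g.ndim != 1:
            raise DataError("values_g must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.values_g.shape[0]


def read_raw_csv(path: str | Path) -> RawRecording:
    """Read a raw tri-axial accelerometer CSV.

    The sample rate is taken from the ``# sample_rate_hz=`` metadata line when
    present and cross-checked against the rate inferred from the first two
    timestamps; a disagreement above 1% is rejected.

    Raises
    ------
    FormatError
        Missing/incorrect header columns.
    DataError
        Non-monotone timestamps or metadata/timestamp rate mismatch.
    EmptyInputError
        File with no sample rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        if not line:
            raise EmptyInputError(f"{path}: no header row")
        header = tuple(col.strip() for col in line.rstrip("\n").split(","))
        if header != RAW_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(RAW_HEADER)}, got {','.join(header)}"
            )
        frame = pd.read_csv(
            fh,
            names=RAW_HEADER,
            dtype={c: float for c in RAW_HEADER[1:]},
        )
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")

    timestamps = pd.to_datetime(frame["timestamp_iso8601"], format="ISO8601")
    if len(timestamps) >= 2:
        deltas = timestamps.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            raise DataError(f"{path}: timestamps are not strictly increasing")
        inferred_hz = 1.0 / deltas.iloc[0].total_seconds()
    else:
        inferred_hz = None

    if "sample_rate_hz" in meta:
        rate = float(meta["sample_rate_hz"])
        if inferred_hz is not None and abs(inferred_hz - rate) / rate > 0.01:
            raise DataError(
                f"{path}: metadata rate {rate} Hz disagrees with timestamp "
                f"spacing ({inferred_hz:.4g} Hz) by more than 1%"
            )
    elif inferred_hz is not None:
        rate = inferred_hz
    else:
        raise FormatError(f"{path}: single row and no sample_rate_hz metadata")

    samples = frame[list(RAW_HEADER[1:])].to_numpy(dtype=float)
    return RawRecording(
        start_time=timestamps.iloc[0].to_pydatetime(),
        sample_rate_hz=rate,
        samples=samples,
        dynamic_range_g=float(meta.get("dynamic_range_g", 8.0)),
        device_label=meta.get("device_label", ""),
    )


def write_raw_csv(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording in the documented dialect (6 decimal places of g)."""
    if recording.n_samples == 0:
        raise EmptyInputError("refusing to write a recording with 0 samples")
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# sample_rate_hz={recording.sample_rate_hz!r}\n")
    buf.write(f"# dynamic_range_g={recording.dynamic_range_g!r}\n")
    if recording.device_label:
        buf.write(f"# device_label={recording.device_label}\n")
    buf.write(",".join(RAW_HEADER) + "\n")
    stamps = recording.times().strftime("%Y-%m-%dT%H:%M:%S.%f")
    cols = [np.char.mod(f"%.{RAW_DECIMALS}f", recording.samples[:, k]) for k in range(3)]
    rows = np.char.add(
        np.char.add(np.asarray(stamps, dtype=str) + ",", cols[0]),
        np.char.add("," + cols[1], "," + cols[2]),
    )
    buf.write("\n".join(rows.tolist()) + "\n")
    path.write_text(buf.getvalue())
    return path


def resample_linear(recording: RawRecording, target_hz: float) -> RawRecording:
    """Resample each axis by linear interpolation onto a uniform target grid.

    Output instants are ``k / target_hz`` for ``k = 0 .. floor(T * target_hz)``
    where ``T`` is the time of the last input sample, so the output never
    extrapolates beyond the input span.
    """
    if recording.n_samples < 2:
        raise DataError("resampling requires at least 2 samples")
    if not target_hz > 0:
        raise DataError("target_hz must be positive")
    src_t = np.arange(recording.n_samples) / recording.sample_rate_hz
    n_out = int(np.floor(src_t[-1] * target_hz)) + 1
    dst_t = np.arange(n_out) / target_hz
    out = np.empty((n_out, 3), dtype=float)
    for axis in range(3):
        out[:, axis] = np.interp(dst_t, src_t, recording.samples[:, axis])
    return replace(recording, sample_rate_hz=float(target_hz), samples=out)


def vector_magnitude(recording: RawRecording) -> MagnitudeSeries:
    """Per-sample Euclidean norm across the three axes (gravity included)."""
    if recording.n_samples == 0:
        raise EmptyInputError("recording has no samples")
    x, y, z = (recording.samples[:, k] for k in range(3))
    return MagnitudeSeries(
        start_time=recording.start_time,
        sample_rate_hz=recording.sample_rate_hz,
        values_g=np.sqrt(x * x + y * y + z * z),
    )


def resample_magnitude(mag: MagnitudeSeries, target_hz: float) -> MagnitudeSeries:
    """Linear-interpolate a magnitude series onto a uniform target grid."""
    if mag.n_samples < 2:
        raise DataError("resampling requires at least 2 samples")
    if target_hz == mag.sample_rate_hz:
        return MagnitudeSeries(mag.start_time, mag.sample_rate_hz, mag.values_g.copy())
    src_t = np.arange(mag.n_samples) / mag.sample_rate_hz
    n_out = int(np.floor(src_t[-1] * target_hz)) + 1
    dst_t = np.arange(n_out) / target_hz
    return MagnitudeSeries(
        start_time=mag.start_time,
        sample_rate_hz=float(target_hz),
        values_g=np.interp(dst_t, src_t, mag.values_g),
    )


def enmo_epochs(
    recording: RawRecording, epoch_s: float = 5.0
) -> list[tuple[datetime, float]]:
    """Epoch-averaged Euclidean-norm-minus-one in mg.

    Per sample, ``max(norm - 1, 0)``; negatives are truncated to zero before
    averaging.  Trailing partial epochs are discarded, never padded.
    """
    if not epoch_s > 0:
        raise DataError("epoch_s must be positive")
    mag = vector_magnitude(recording)
    per_epoch = int(round(epoch_s * recording.sample_rate_hz))
    n_epochs = mag.n_samples // per_epoch
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; no ENMO epochs produced")
        return []
    enmo = np.maximum(mag.values_g - 1.0, 0.0)
    means = enmo[: n_epochs * per_epoch].reshape(n_epochs, per_epoch).mean(axis=1)
    start = pd.Timestamp(recording.start_time)
    return [
        ((start + pd.Timedelta(seconds=i * epoch_s)).to_pydatetime(), float(m * 1000.0))
        for i, m in enumerate(means)
    ]


def apply_axis_correction(
    recording: RawRecording,
    offset_g: tuple[float, float, float] = (0.0, 0.0, 0.0),
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RawRecording:
    """Apply a pre-supplied per-axis offset/scale correction.

    Hook for externally estimated calibration (``corrected = raw * scale +
    offset``); this package does not estimate calibration coefficients.
    """
    corrected = recording.samples * np.asarray(scale, float) + np.asarray(offset_g, float)
    return replace(recording, samples=corrected)
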