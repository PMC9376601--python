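"""Reading, writing and resampling six-channel inertial recordings.

A recording carries three linear-acceleration channels (``la_x/y/z``,
m/s^2) and three angular-velocity channels (``av_x/y/z``, rad/s) at a
common sampling rate near 100 Hz.  CSV column naming and gyro units vary
between acquisition apps, so ingestion goes through a small dialect
registry; after ingestion every recording is in SI units, and gaps or
jitter in the timestamps are resolved by linear resampling onto a uniform
grid before spectral analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError, ParameterError

__all__ = [
    "CHANNELS",
    "LINEAR_CHANNELS",
    "ANGULAR_CHANNELS",
    "Recording",
    "Dialect",
    "DIALECTS",
    "read_recording",
    "write_recording",
    "resample_uniform",
    "ControlReference",
    "write_control_reference",
    "read_control_reference",
]

LINEAR_CHANNELS = ("la_x", "la_y", "la_z")
ANGULAR_CHANNELS = ("av_x", "av_y", "av_z")
CHANNELS = LINEAR_CHANNELS + ANGULAR_CHANNELS

CANONICAL_UNITS = {name: "m/s^2" for name in LINEAR_CHANNELS}
CANONICAL_UNITS.update({name: "rad/s" for name in ANGULAR_CHANNELS})

#: Minimum duration (in window lengths of the default 8-s analysis window)
MIN_DURATION_S = 16.0
MIN_RATE_HZ = 20.0

SENSORS = ("finger", "phone")
POSITIONS = ("P1", "P2", "unknown")


@dataclass
class Recording:
    """Uniformly sampled six-channel inertial recording in SI units.

    ``timestamps`` (seconds, arbitrary origin) are retained from ingestion
    until :func:`resample_uniform` replaces them with a uniform grid; all
    spectral code assumes uniform sampling at ``rate``.
    """

    channels: dict[str, np.ndarray]
    rate: float
    sensor: str = "phone"
    position: str = "unknown"
    subject_id: str = ""
    timestamps: np.ndarray | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if not self.units:
            self.units = {k: CANONICAL_UNITS.get(k, "") for k in self.channels}
        if self.sensor not in SENSORS:
            raise ParameterError(f"sensor must be one of {SENSORS}")
        if self.position not in POSITIONS:
            raise ParameterError(f"position must be one of {POSITIONS}")
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) != 1:
            raise DataError("all channels must have the same length")
        (n,) = lengths
        if self.rate <= MIN_RATE_HZ:
            raise ParameterError(
                f"sampling rate must exceed {MIN_RATE_HZ} Hz (got {self.rate})"
            )
        if n < self.rate * MIN_DURATION_S:
            raise DataError(
                f"recording too short: {n} samples at {self.rate} Hz; "
                f"need at least {MIN_DURATION_S} s "
                f"({int(self.rate * MIN_DURATION_S)} samples)"
            )
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.size != n:
                raise DataError("timestamps length does not match channels")

    @property
    def channel_names(self) -> tuple[str, ...]:
        """Channels present, in canonical order (extras appended)."""
        present = [c for c in CHANNELS if c in self.channels]
        present += [c for c in self.channels if c not in CHANNELS]
        return tuple(present)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class Dialect:
    """Maps on-disk CSV columns and units to the canonical layout."""

    name: str
    time_column: str
    column_map: dict[str, str]  # canonical channel -> file column
    gyro_unit: str = "rad/s"  # "rad/s" or "deg/s"

    def file_column(self, channel: str) -> str:
        return self.column_map[channel]


DIALECTS: dict[str, Dialect] = {
    # smartphone-app export: SI units, canonical column names
    "phone": Dialect(
        name="phone",
        time_column="t",
        column_map={c: c for c in CHANNELS},
    ),
    # vendor-style miniature IMU export: gyro in deg/s
    "lpms": Dialect(
        name="lpms",
        time_column="TimeStamp",
        column_map={
            "la_x": "LinAccX",
            "la_y": "LinAccY",
            "la_z": "LinAccZ",
            "av_x": "GyroX",
            "av_y": "GyroY",
            "av_z": "GyroZ",
        },
        gyro_unit="deg/s",
    ),
}


def _get_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ParameterError(
            f"unknown dialect {dialect!r}; available: {sorted(DIALECTS)}"
        ) from None


def read_recording(
    path,
    dialect: str | Dialect = "phone",
    *,
    sensor: str | None = None,
    position: str = "unknown",
    subject_id: str = "",
) -> Recording:
    """Read a CSV recording; convert to SI units; keep raw timestamps.

    The sampling rate is inferred from the timestamp span.  Unit
    conversion (deg/s -> rad/s for dialects that need it) happens exactly
    once, here; the returned recording is tagged with canonical units.
    """
    d = _get_dialect(dialect)
    df = pd.read_csv(path)
    if d.time_column not in df.columns:
        raise FormatError(f"missing time column {d.time_column!r}")
    for channel in CHANNELS:
        if d.file_column(channel) not in df.columns:
            raise FormatError(f"missing channel {channel}")
    t = df[d.time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("recording must contain at least two samples")
    if not np.all(np.diff(t) > 0):
        raise DataError("timestamps are not strictly increasing")
    gyro_scale = np.pi / 180.0 if d.gyro_unit == "deg/s" else 1.0
    channels = {}
    for channel in CHANNELS:
        col = df[d.file_column(channel)].to_numpy(dtype=float)
        if channel in ANGULAR_CHANNELS:
            col = col * gyro_scale
        channels[channel] = col
    rate = (t.size - 1) / (t[-1] - t[0])
    return Recording(
        channels=channels,
        rate=rate,
        sensor=sensor if sensor is not None else ("finger" if d.name == "lpms" else "phone"),
        position=position,
        subject_id=subject_id,
        timestamps=t,
    )


def write_recording(recording: Recording, path, dialect: str | Dialect = "phone") -> None:
    """Write a recording as CSV in the given dialect (inverse of read)."""
    d = _get_dialect(dialect)
    t = (
        recording.timestamps
        if recording.timestamps is not None
        else np.arange(recording.n_samples) / recording.rate
    )
    gyro_scale = 180.0 / np.pi if d.gyro_unit == "deg/s" else 1.0
    data = {d.time_column: t}
    for channel in CHANNELS:
        col = recording.channels[channel]
        if channel in ANGULAR_CHANNELS:
            col = col * gyro_scale
        data[d.file_column(channel)] = col
    pd.DataFrame(data).to_csv(path, index=False)


def resample_uniform(recording: Recording, target_rate: float) -> Recording:
    """Linearly interpolate all channels onto a uniform grid.

    The grid spans [t0, t_end] at ``target_rate``; with the 10 Hz band of
    interest sampled at >=100 Hz, linear interpolation error is negligible
    against sensor noise.
    """
    if target_rate <= MIN_RATE_HZ:
        raise ParameterError(
            f"target_rate must exceed {MIN_RATE_HZ} Hz (got {target_rate})"
        )
    t = (
        recording.timestamps
        if recording.timestamps is not None
        else np.arange(recording.n_samples) / recording.rate
    )
    if t.size < 2:
        raise DataError("resampling requires at least two samples")
    # epsilon guards against float truncation on exactly-representable spans
    n_out = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_rate
    channels = {
        name: np.interp(grid, t, samples)
        for name, samples in recording.channels.items()
    }
    return replace(
        recording,
        channels=channels,
        rate=float(target_rate),
        timestamps=grid,
    )


@dataclass(frozen=True)
class ControlReference:
    """Population-average control tremor index used for dB normalization.

    ``pipeline_config_hash`` binds the reference to the spectral/index
    configuration it was computed under; scores are only comparable in dB
    when computed with the same configuration.
    """

    mean_index: float
    n_subjects: int
    band: tuple[float, float]
    pipeline_config_hash: str

    def __post_init__(self) -> None:
        if self.mean_index <= 0:
            raise ParameterError("mean_index must be positive")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be at least 1")
        object.__setattr__(self, "band", tuple(float(b) for b in self.band))

    def to_json_dict(self) -> dict:
        return {
            "mean_index": self.mean_index,
            "n_subjects": self.n_subjects,
            "band": list(self.band),
            "pipeline_config_hash": self.pipeline_config_hash,
        }


def write_control_reference(
    scores,
    path=None,
    *,
    band: tuple[float, float] = (3.5, 10.0),
    pipeline_config_hash: str = "",
) -> ControlReference:
    """Build a control reference (arithmetic mean of control indices) and
    optionally serialize it to JSON."""
    scores = [float(s) for s in scores]
    if not scores:
        raise ParameterError("need at least one control score")
    if any(s <= 0 for s in scores):
        raise ParameterError("all control scores must be positive")
    ref = ControlReference(
        mean_index=float(np.mean(scores)),
        n_subjects=len(scores),
        band=band,
        pipeline_config_hash=pipeline_config_hash,
    )
    if path is not None:
        Path(path).write_text(json.dumps(ref.to_json_dict(), indent=2) + "\n")
    return ref


def read_control_reference(path) -> ControlReference:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"control reference is not valid JSON: {exc}") from exc
    try:
        return ControlReference(
            mean_index=d["mean_index"],
            n_subjects=d["n_subjects"],
            band=tuple(d["band"]),
            pipeline_config_hash=d["pipeline_config_hash"],
        )
    except KeyError as exc:
        raise FormatError(f"control reference missing field {exc}") from exc
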