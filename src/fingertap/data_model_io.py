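"""Domain types and CSV/YAML plumbing for tapping-test recordings.

The tapping test (TT) is administered in four variants: simultaneous or
alternating tapping of the index and middle fingers of the dominant hand
(UniSIM / UniALT), and of the two index fingers across hands
(BimSIM / BimALT).  Each finger wears a small IMU whose accelerometer is
sampled at 120 Hz over a full scale of +/-8 g; one trial therefore yields
two tri-axial traces that were time-synchronised at acquisition.

This module defines the validated containers for those recordings
(:class:`AccelTrace`, :class:`TrialRecord`), the analysis configuration
(:class:`SessionConfig`), and readers/writers for a neutral CSV dialect
(header row, comma separated, UTF-8).  The vendor export format is not
standardised, so the reader accepts a ``column_map`` to adapt to other
headers, a time-unit flag (seconds, milliseconds, or sample counter) and
an acceleration-unit flag (g or m/s^2, converted with g = 9.81 m/s^2).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, DomainError, FormatError

__all__ = [
    "FingerLabel",
    "TestType",
    "AccelTrace",
    "TrialRecord",
    "SessionConfig",
    "read_trace_csv",
    "write_trace_csv",
    "write_metrics_table",
    "read_metrics_table",
    "GRAVITY_MS2",
]

#: Standard gravity used to convert accelerations expressed in m/s^2 into g.
GRAVITY_MS2 = 9.81

#: Relative tolerance on inter-sample spacing versus 1/sampling_rate.
SAMPLING_RTOL = 0.01


class FingerLabel(str, enum.Enum):
    """Instrumented finger: dominant-hand index/middle, or left/right index."""

    INDEX_DOM = "index_dom"
    MIDDLE_DOM = "middle_dom"
    INDEX_RIGHT = "index_right"
    INDEX_LEFT = "index_left"


class TestType(str, enum.Enum):
    """The four tapping-test variants."""

    UNISIM = "UniSIM"
    UNIALT = "UniALT"
    BIMSIM = "BimSIM"
    BIMALT = "BimALT"

    @property
    def is_bimanual(self) -> bool:
        return self in (TestType.BIMSIM, TestType.BIMALT)

    @property
    def is_alternate(self) -> bool:
        return self in (TestType.UNIALT, TestType.BIMALT)

    @property
    def finger_pair(self) -> frozenset[FingerLabel]:
        """The finger pair this test instruments."""
        if self.is_bimanual:
            return frozenset({FingerLabel.INDEX_RIGHT, FingerLabel.INDEX_LEFT})
        return frozenset({FingerLabel.INDEX_DOM, FingerLabel.MIDDLE_DOM})

    @property
    def manual_condition(self) -> str:
        """'uni' or 'bim'; alternation criteria reference the simultaneous
        test of the same manual condition."""
        return "bim" if self.is_bimanual else "uni"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass
class AccelTrace:
    """One finger's uniformly sampled tri-axial acceleration record.

    Parameters
    ----------
    sensor_id : str
        Identifier of the IMU that produced the record.
    finger_label : FingerLabel
        Which finger wore the sensor.
    sampling_rate : float
        Nominal sampling rate in Hz (default acquisition uses 120 Hz).
    timestamps : array of float
        Sample times in seconds, strictly increasing, uniform to within
        1% of ``1/sampling_rate``.
    ax, ay, az : array of float
        Acceleration along each sensor axis, in g.
    full_scale : float
        Accelerometer full scale in g; samples must lie within it.
    """

    sensor_id: str
    finger_label: FingerLabel
    sampling_rate: float
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    full_scale: float = 8.0

    def __post_init__(self) -> None:
        self.finger_label = FingerLabel(self.finger_label)
        if not self.sampling_rate > 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.full_scale > 0:
            raise ConfigError(f"full_scale must be > 0, got {self.full_scale}")
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        n = self.timestamps.size
        if n < 2:
            raise DataError(f"trace must have at least 2 samples, got {n}")
        for name in ("ax", "ay", "az"):
            if getattr(self, name).size != n:
                raise DataError(
                    f"{name} length {getattr(self, name).size} != timestamps length {n}"
                )
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise DataError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
        nominal = 1.0 / self.sampling_rate
        if np.any(np.abs(dt - nominal) > SAMPLING_RTOL * nominal):
            measured = 1.0 / float(np.median(dt))
            raise DataError(
                "irregular sampling: measured rate "
                f"{measured:.3f} Hz vs declared {self.sampling_rate:g} Hz "
                f"(tolerance {100 * SAMPLING_RTOL:.0f}%)"
            )
        amax = max(
            float(np.max(np.abs(a))) for a in (self.ax, self.ay, self.az)
        )
        if amax > self.full_scale:
            raise DataError(
                f"acceleration {amax:.3f} g exceeds full scale +/-{self.full_scale:g} g"
            )

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def axis(self, name: str) -> np.ndarray:
        """Return the 1-D signal of axis ``'x'``, ``'y'`` or ``'z'``."""
        try:
            return {"x": self.ax, "y": self.ay, "z": self.az}[name]
        except KeyError:
            raise DomainError(f"unknown axis {name!r}; expected 'x', 'y' or 'z'")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccelTrace):
            return NotImplemented
        return (
            self.sensor_id == other.sensor_id
            and self.finger_label == other.finger_label
            and self.sampling_rate == other.sampling_rate
            and self.full_scale == other.full_scale
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.ax, other.ax)
            and np.array_equal(self.ay, other.ay)
            and np.array_equal(self.az, other.az)
        )


@dataclass
class TrialRecord:
    """One test execution: two finger traces plus session metadata."""

    participant_id: str
    test_type: TestType
    trace_1: AccelTrace
    trace_2: AccelTrace
    duration: float
    metadata: dict = field(default_factory=dict)

    #: Minimum fraction of `duration` over which the two traces must overlap.
    MIN_OVERLAP_FRACTION = 0.9

    def __post_init__(self) -> None:
        self.test_type = TestType(self.test_type)
        if not self.duration > 0:
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        if self.trace_1.finger_label == self.trace_2.finger_label:
            raise DataError(
                f"both traces labelled {self.trace_1.finger_label.value}; "
                "a trial needs two distinct fingers"
            )
        labels = {self.trace_1.finger_label, self.trace_2.finger_label}
        if labels != self.test_type.finger_pair:
            expected = sorted(f.value for f in self.test_type.finger_pair)
            raise DataError(
                f"test {self.test_type.value} expects fingers {expected}, "
                f"got {sorted(f.value for f in labels)}"
            )
        t1, t2 = self.trace_1.timestamps, self.trace_2.timestamps
        overlap = min(t1[-1], t2[-1]) - max(t1[0], t2[0])
        if overlap < self.MIN_OVERLAP_FRACTION * self.duration:
            raise DataError(
                f"traces overlap for {overlap:.2f} s, need at least "
                f"{self.MIN_OVERLAP_FRACTION * self.duration:.2f} s of the "
                f"{self.duration:g} s trial"
            )


@dataclass
class SessionConfig:
    """Analysis configuration for a recording session.

    The defaults mirror the study conditions: 0.1 s simultaneity threshold,
    5 s excursion windows, +/-8 g full scale, 120 Hz sampling.
    """

    # Detection parameters are stored loosely here to avoid a circular
    # import; `detection_params()` materialises the typed object.
    min_prominence: float = 0.5
    min_separation: float = 0.08
    smoothing_halfwidth: int = 0
    polarity: str = "auto"
    simultaneity_threshold: float = 0.1
    excursion_window: float = 5.0
    full_scale: float = 8.0
    sampling_rate_expected: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "min_prominence",
            "simultaneity_threshold",
            "excursion_window",
            "full_scale",
            "sampling_rate_expected",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.min_separation < 0:
            raise ConfigError("min_separation must be >= 0")
        if self.smoothing_halfwidth < 0:
            raise ConfigError("smoothing_halfwidth must be >= 0")

    def detection_params(self):
        from .tap_detection import DetectionParams

        return DetectionParams(
            min_prominence=self.min_prominence,
            min_separation=self.min_separation,
            smoothing_halfwidth=self.smoothing_halfwidth,
            polarity=self.polarity,
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SessionConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"time": "time", "ax": "ax", "ay": "ay", "az": "az"}


def read_trace_csv(
    path: Union[str, Path],
    finger_label: FingerLabel,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    sampling_rate: Optional[float] = None,
    time_unit: str = "s",
    accel_unit: str = "g",
    sensor_id: Optional[str] = None,
    full_scale: float = 8.0,
) -> AccelTrace:
    """Read a per-finger trace from CSV and return a validated AccelTrace.

    Parameters
    ----------
    path : path
        CSV file with a header row naming a time column and three
        acceleration columns (defaults: ``time, ax, ay, az``).
    finger_label : FingerLabel
        Label to attach to the trace.
    column_map : mapping, optional
        Maps the roles ``time``/``ax``/``ay``/``az`` to the actual column
        names in the file.
    sampling_rate : float, optional
        Declared rate in Hz.  Required when ``time_unit='samples'``;
        otherwise inferred from the median time step when omitted.
    time_unit : {'s', 'ms', 'samples'}
        Unit of the time column.  ``'samples'`` interprets it as a sample
        counter converted with the declared ``sampling_rate``.
    accel_unit : {'g', 'm/s2'}
        Unit of the acceleration columns; m/s^2 is divided by 9.81.
    sensor_id : str, optional
        Defaults to the file stem.

    Timestamps are shifted so the record starts at 0 s.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for role, name in cols.items():
        if name not in df.columns:
            raise FormatError(
                f"{path}: missing column {name!r} (role {role!r}); "
                f"available: {list(df.columns)}"
            )
    time = np.asarray(df[cols["time"]], dtype=float)
    if time_unit == "s":
        pass
    elif time_unit == "ms":
        time = time / 1000.0
    elif time_unit == "samples":
        if sampling_rate is None:
            raise ConfigError("time_unit='samples' requires a declared sampling_rate")
        time = time / sampling_rate
    else:
        raise ConfigError(f"unknown time_unit {time_unit!r}")

    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise DataError(f"{path}: non-monotone time at row {int(bad[0]) + 1}")
    if sampling_rate is None:
        if dt.size == 0:
            raise DataError(f"{path}: need at least 2 rows")
        sampling_rate = 1.0 / float(np.median(dt))

    scale = 1.0 if accel_unit == "g" else None
    if accel_unit == "m/s2":
        scale = 1.0 / GRAVITY_MS2
    if scale is None:
        raise ConfigError(f"unknown accel_unit {accel_unit!r}")

    return AccelTrace(
        sensor_id=sensor_id if sensor_id is not None else path.stem,
        finger_label=finger_label,
        sampling_rate=float(sampling_rate),
        timestamps=time - time[0],
        ax=np.asarray(df[cols["ax"]], dtype=float) * scale,
        ay=np.asarray(df[cols["ay"]], dtype=float) * scale,
        az=np.asarray(df[cols["az"]], dtype=float) * scale,
        full_scale=full_scale,
    )


def write_trace_csv(trace: AccelTrace, path: Union[str, Path]) -> Path:
    """Write a trace to the neutral CSV dialect, full float precision.

    The output round-trips through :func:`read_trace_csv` to an identical
    AccelTrace provided the trace starts at t = 0 (the reader re-references
    time to the first sample).
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": trace.timestamps,
            "ax": trace.ax,
            "ay": trace.ay,
            "az": trace.az,
        }
    )
    # repr-based formatting preserves doubles exactly across the round trip
    df.to_csv(path, index=False, float_format=None)
    return path


def write_metrics_table(
    records: Sequence[Mapping[str, object]],
    path: Union[str, Path],
    columns: Optional[Sequence[str]] = None,
) -> Path:
    """Persist per-trial metric rows as a tidy CSV.

    One row per (participant, test, finger or finger pair); the column
    order is the key order of the first record (or ``columns`` when given)
    and is what the header row documents.  All records must share the same
    keys.  An empty record list yields a header-only file (``columns``
    supplies the header in that case).
    """
    path = Path(path)
    if len(records) == 0:
        pd.DataFrame(columns=list(columns or [])).to_csv(path, index=False)
        return path
    keys = list(columns) if columns is not None else list(records[0].keys())
    for i, rec in enumerate(records):
        if set(rec.keys()) != set(keys):
            raise DataError(
                f"heterogeneous metric rows: row {i} keys {list(rec.keys())} "
                f"!= row 0 keys {keys}"
            )
    df = pd.DataFrame.from_records(list(records), columns=keys)
    df.to_csv(path, index=False)
    return path


def read_metrics_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics_table`."""
    return pd.read_csv(path)
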