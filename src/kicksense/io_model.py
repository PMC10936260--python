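"""Data model and on-disk artifacts.

Defines the in-memory containers used throughout the pipeline (sensor
streams, recordings, one-minute segments, per-segment feature rows, session
summaries) plus the plain-text readers/writers for each of them.

Units are fixed internally: time in seconds from session start, angular rate
in deg/s, specific force in g, angles in degrees, ages in weeks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SIDES = ("left", "right")
LIMB_SEGMENTS = ("thigh", "shin", "foot")
SENSOR_IDS = tuple(f"{side}_{seg}" for side in SIDES for seg in LIMB_SEGMENTS)

#: anatomical degrees of freedom of one leg, in reporting order
DOFS = ("hip_flex", "hip_abd", "hip_rot", "knee_flex", "ankle_flex", "ankle_inv")

#: sentinel written to feature tables where a metric is undefined
#: (e.g. no kick cycles in a segment -> inter-joint correlations undefined)
UNDEFINED_TOKEN = "undef"

_SENSOR_COLUMNS = ("t", "gx", "gy", "gz", "ax", "ay", "az")

# unit conversion factors into the internal deg/s and g conventions
_GYRO_UNITS = {"deg/s": 1.0, "dps": 1.0, "rad/s": 180.0 / math.pi}
_ACCEL_UNITS = {"g": 1.0, "m/s2": 1.0 / 9.80665, "m/s^2": 1.0 / 9.80665}


class IngestionError(ValueError):
    """Raised when an on-disk artifact violates the data model."""


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SensorStream:
    """One sensor's synchronized gyroscope/accelerometer series.

    Attributes
    ----------
    sensor_id : str
        One of ``left_thigh ... right_foot``.
    sample_rate : float
        Sampling frequency in Hz.
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    gyro : ndarray, shape (n, 3)
        Angular rate in deg/s.
    accel : ndarray, shape (n, 3)
        Specific force in g.
    """

    sensor_id: str
    sample_rate: float
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_id not in SENSOR_IDS:
            raise ValueError(f"unknown sensor_id {self.sensor_id!r}")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        self.t = _as_float_array(self.t, "t", 1)
        self.gyro = _as_float_array(self.gyro, "gyro", 2)
        self.accel = _as_float_array(self.accel, "accel", 2)
        n = len(self.t)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro and accel must have shape (len(t), 3)")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            row = int(np.argmin(np.diff(self.t) > 0)) + 2
            raise IngestionError(f"non-monotone time at row {row}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def side(self) -> str:
        return self.sensor_id.split("_")[0]

    @property
    def limb_segment(self) -> str:
        return self.sensor_id.split("_")[1]

    def slice(self, start: int, stop: int) -> "SensorStream":
        """View of samples ``[start, stop)`` as a new stream."""
        return SensorStream(
            sensor_id=self.sensor_id,
            sample_rate=self.sample_rate,
            t=self.t[start:stop],
            gyro=self.gyro[start:stop],
            accel=self.accel[start:stop],
        )

    def replace(self, gyro: np.ndarray | None = None,
                accel: np.ndarray | None = None) -> "SensorStream":
        return SensorStream(
            sensor_id=self.sensor_id,
            sample_rate=self.sample_rate,
            t=self.t,
            gyro=self.gyro if gyro is None else gyro,
            accel=self.accel if accel is None else accel,
        )


@dataclass
class Recording:
    """One kicking session: six sensor streams plus session metadata."""

    infant_id: str
    status: str  # "term" | "preterm"
    gestational_age: float  # weeks
    age_at_test: float  # weeks, nearest half week
    streams: dict  # sensor_id -> SensorStream
    calibration_window: tuple  # (start, end) seconds of the stationary hold
    adjusted_age: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("term", "preterm"):
            raise ValueError(f"status must be 'term' or 'preterm', got {self.status!r}")
        missing = [s for s in SENSOR_IDS if s not in self.streams]
        if missing:
            raise IngestionError(f"missing sensor {missing[0]}")
        if len(self.streams) != 6:
            extra = set(self.streams) - set(SENSOR_IDS)
            raise IngestionError(f"unexpected sensors {sorted(extra)}")
        rates = {s.sample_rate for s in self.streams.values()}
        if len(rates) != 1:
            raise IngestionError(f"mismatched sample rates {sorted(rates)}")
        lo = max(s.t[0] for s in self.streams.values())
        hi = min(s.t[-1] for s in self.streams.values())
        c0, c1 = self.calibration_window
        if not (c1 > c0):
            raise ValueError("calibration window must have positive length")
        if c0 < lo - 1e-9 or c1 > hi + 1e-9:
            raise IngestionError(
                f"calibration window ({c0}, {c1}) outside common span ({lo}, {hi})"
            )
        if self.status == "term":
            if self.adjusted_age is not None:
                warnings.warn("adjusted_age given for a term infant; ignored")
                self.adjusted_age = None
        elif self.adjusted_age is None:
            self.adjusted_age = self.age_at_test - (40.0 - self.gestational_age)

    @property
    def sample_rate(self) -> float:
        return next(iter(self.streams.values())).sample_rate

    def leg_streams(self, side: str) -> tuple:
        """(thigh, shin, foot) streams of one leg."""
        return tuple(self.streams[f"{side}_{seg}"] for seg in LIMB_SEGMENTS)


@dataclass
class Segment:
    """One fixed-length analysis window of a preprocessed recording."""

    index: int
    start_time: float  # seconds, session clock
    n_samples: int
    sample_rate: float
    streams: dict  # sensor_id -> SensorStream slice

    def __post_init__(self) -> None:
        for s in self.streams.values():
            if len(s) != self.n_samples:
                raise ValueError("segment stream length mismatch")

    def leg_streams(self, side: str) -> tuple:
        return tuple(self.streams[f"{side}_{seg}"] for seg in LIMB_SEGMENTS)


def _is_undefined(v: float) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass
class FeatureRow:
    """All segment-level kinematic metrics for one one-minute segment.

    Frequencies are unitless fractions of segment samples, durations in
    seconds, accelerations in g, excursions in degrees.  Metrics that cannot
    be computed for a segment (accelerations with no active samples,
    inter-joint correlations with no kick cycles) are NaN and serialize to
    an explicit ``undef`` token.
    """

    segment_index: int
    F_act: float
    F_rest: float
    F_B: float
    F_UL: float
    F_UR: float
    F_UP: float
    D_avg_kick: float
    D_max_kick: float
    D_avg_rest: float
    D_max_rest: float
    A_avg: float
    A_peak: float
    C_HK: float
    C_HA: float
    C_KA: float
    Emax_pos: dict = field(default_factory=dict)  # dof -> deg
    Emax_neg: dict = field(default_factory=dict)  # dof -> deg
    predominant_leg: str = "right"
    K: int = 0

    _TOL = 1e-9

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tol = self._TOL
        for name in ("F_act", "F_rest", "F_B", "F_UL", "F_UR", "F_UP"):
            v = getattr(self, name)
            if not (-tol <= v <= 1 + tol):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.F_B + self.F_UL + self.F_UR - self.F_act) > tol:
            raise ValueError("F_B + F_UL + F_UR != F_act")
        if abs(self.F_act + self.F_rest - 1.0) > tol:
            raise ValueError("F_act + F_rest != 1")
        if abs(self.F_UP - max(self.F_UL, self.F_UR)) > tol:
            raise ValueError("F_UP != max(F_UL, F_UR)")
        for avg, mx in (("D_avg_kick", "D_max_kick"), ("D_avg_rest", "D_max_rest")):
            a, m = getattr(self, avg), getattr(self, mx)
            if a < -tol or m < a - tol:
                raise ValueError(f"need {mx} >= {avg} >= 0, got {m}, {a}")
        if not _is_undefined(self.A_avg):
            if self.A_avg < -tol or self.A_peak < self.A_avg - tol:
                raise ValueError("need A_peak >= A_avg >= 0")
        for name in ("C_HK", "C_HA", "C_KA"):
            v = getattr(self, name)
            if not _is_undefined(v) and not (-1 - tol <= v <= 1 + tol):
                raise ValueError(f"{name}={v} outside [-1, 1]")
        for d in DOFS:
            for store, lab in ((self.Emax_pos, "Emax_pos"), (self.Emax_neg, "Emax_neg")):
                v = store.get(d, 0.0)
                if v < -tol:
                    raise ValueError(f"{lab}[{d}]={v} negative")
        if self.predominant_leg not in SIDES:
            raise ValueError(f"bad predominant_leg {self.predominant_leg!r}")
        if self.K < 0:
            raise ValueError("K must be >= 0")

    # -- tabular flattening -------------------------------------------------

    @staticmethod
    def column_names() -> list:
        cols = [
            "segment_index", "F_act", "F_rest", "F_B", "F_UL", "F_UR", "F_UP",
            "D_avg_kick", "D_max_kick", "D_avg_rest", "D_max_rest",
            "A_avg", "A_peak", "C_HK", "C_HA", "C_KA",
        ]
        cols += [f"Emax_pos_{d}" for d in DOFS]
        cols += [f"Emax_neg_{d}" for d in DOFS]
        cols += ["predominant_leg", "K"]
        return cols

    def to_dict(self) -> dict:
        d = {
            "segment_index": self.segment_index,
            "F_act": self.F_act, "F_rest": self.F_rest, "F_B": self.F_B,
            "F_UL": self.F_UL, "F_UR": self.F_UR, "F_UP": self.F_UP,
            "D_avg_kick": self.D_avg_kick, "D_max_kick": self.D_max_kick,
            "D_avg_rest": self.D_avg_rest, "D_max_rest": self.D_max_rest,
            "A_avg": self.A_avg, "A_peak": self.A_peak,
            "C_HK": self.C_HK, "C_HA": self.C_HA, "C_KA": self.C_KA,
        }
        for dof in DOFS:
            d[f"Emax_pos_{dof}"] = self.Emax_pos.get(dof, 0.0)
            d[f"Emax_neg_{dof}"] = self.Emax_neg.get(dof, 0.0)
        d["predominant_leg"] = self.predominant_leg
        d["K"] = self.K
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRow":
        return cls(
            segment_index=int(d["segment_index"]),
            F_act=float(d["F_act"]), F_rest=float(d["F_rest"]),
            F_B=float(d["F_B"]), F_UL=float(d["F_UL"]), F_UR=float(d["F_UR"]),
            F_UP=float(d["F_UP"]),
            D_avg_kick=float(d["D_avg_kick"]), D_max_kick=float(d["D_max_kick"]),
            D_avg_rest=float(d["D_avg_rest"]), D_max_rest=float(d["D_max_rest"]),
            A_avg=float(d["A_avg"]), A_peak=float(d["A_peak"]),
            C_HK=float(d["C_HK"]), C_HA=float(d["C_HA"]), C_KA=float(d["C_KA"]),
            Emax_pos={dof: float(d[f"Emax_pos_{dof}"]) for dof in DOFS},
            Emax_neg={dof: float(d[f"Emax_neg_{dof}"]) for dof in DOFS},
            predominant_leg=str(d["predominant_leg"]),
            K=int(d["K"]),
        )


@dataclass
class SessionSummary:
    """Per-session median of each kinematic feature over retained segments."""

    infant_id: str
    age_at_test: float  # weeks
    features: dict  # feature name -> median (NaN when undefined in all rows)
    n_segments_retained: int


# ---------------------------------------------------------------------------
# sensor CSV
# ---------------------------------------------------------------------------

def _parse_sensor_header(header: str) -> dict:
    """Map canonical column name -> (index, conversion factor)."""
    cols = {}
    for i, raw in enumerate(header.strip().split(",")):
        raw = raw.strip()
        if "[" in raw and raw.endswith("]"):
            name, unit = raw[:-1].split("[", 1)
        else:
            name, unit = raw, None
        name = name.strip()
        if name == "t":
            factor = 1.0
        elif name in ("gx", "gy", "gz"):
            factor = _GYRO_UNITS.get(unit or "deg/s")
            if factor is None:
                raise IngestionError(f"unknown gyro unit {unit!r}")
        elif name in ("ax", "ay", "az"):
            factor = _ACCEL_UNITS.get(unit or "g")
            if factor is None:
                raise IngestionError(f"unknown accel unit {unit!r}")
        else:
            raise IngestionError(f"unknown column {name!r}")
        cols[name] = (i, factor)
    missing = [c for c in _SENSOR_COLUMNS if c not in cols]
    if missing:
        raise IngestionError(f"missing column {missing[0]!r}")
    return cols


def read_sensor_csv(path, sensor_id: str, sample_rate: float | None = None) -> SensorStream:
    """Read one sensor's CSV (columns t,gx,gy,gz,ax,ay,az, one header line).

    Units default to deg/s and g; a column header like ``gx[rad/s]`` or
    ``ax[m/s2]`` requests conversion at the boundary.  The file must contain
    a gap-free, strictly increasing time base; a gap larger than 1.5 sample
    intervals is an ingestion error naming the offending row.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        cols = _parse_sensor_header(header)
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise IngestionError(f"{path.name}: malformed numeric data ({exc})") from exc
    if data.size == 0:
        raise IngestionError(f"{path.name}: no samples")
    get = lambda name: data[:, cols[name][0]] * cols[name][1]
    t = get("t")
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise IngestionError(f"non-monotone time at row {bad[0] + 2}")
        if sample_rate is None:
            sample_rate = 1.0 / np.median(dt)
        gaps = np.nonzero(dt > 1.5 / sample_rate)[0]
        if gaps.size:
            raise IngestionError(
                f"{path.name}: gap of {dt[gaps[0]]:.4f}s at row {gaps[0] + 2}"
            )
    elif sample_rate is None:
        raise IngestionError(f"{path.name}: cannot infer sample rate from one sample")
    gyro = np.column_stack([get("gx"), get("gy"), get("gz")])
    accel = np.column_stack([get("ax"), get("ay"), get("az")])
    return SensorStream(sensor_id=sensor_id, sample_rate=float(sample_rate),
                        t=t, gyro=gyro, accel=accel)


def write_sensor_csv(stream: SensorStream, path) -> None:
    """Write a sensor stream in the canonical CSV dialect (deg/s, g)."""
    data = np.column_stack([stream.t, stream.gyro, stream.accel])
    with open(path, "w") as fh:
        fh.write(",".join(_SENSOR_COLUMNS) + "\n")
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# session manifest
# ---------------------------------------------------------------------------

def read_session(manifest_path) -> Recording:
    """Read a session manifest (YAML) and its six sensor CSVs.

    Expected keys: ``infant_id``, ``status``, ``gestational_age_weeks``,
    ``age_weeks``, optional ``adjusted_age_weeks``, ``sensors`` (mapping of
    the six sensor ids to CSV paths relative to the manifest), and
    ``calibration`` with ``start``/``end`` seconds.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        m = yaml.safe_load(fh)
    if not isinstance(m, dict):
        raise IngestionError(f"{manifest_path.name}: manifest is not a mapping")
    for key in ("infant_id", "status", "gestational_age_weeks", "age_weeks",
                "sensors", "calibration"):
        if key not in m:
            raise IngestionError(f"{manifest_path.name}: missing key {key!r}")
    sensors = m["sensors"]
    missing = [s for s in SENSOR_IDS if s not in sensors]
    if missing:
        raise IngestionError(f"missing sensor {missing[0]}")
    streams = {}
    for sid in SENSOR_IDS:
        p = Path(sensors[sid])
        if not p.is_absolute():
            p = manifest_path.parent / p
        streams[sid] = read_sensor_csv(p, sid)
    cal = m["calibration"]
    adjusted = m.get("adjusted_age_weeks")
    rec = Recording(
        infant_id=str(m["infant_id"]),
        status=str(m["status"]),
        gestational_age=float(m["gestational_age_weeks"]),
        age_at_test=float(m["age_weeks"]),
        streams=streams,
        calibration_window=(float(cal["start"]), float(cal["end"])),
        adjusted_age=None if adjusted is None else float(adjusted),
    )
    if rec.status == "preterm" and adjusted is not None:
        expected = rec.age_at_test - (40.0 - rec.gestational_age)
        if abs(float(adjusted) - expected) > 0.25:
            warnings.warn(
                f"manifest adjusted_age {adjusted} inconsistent with "
                f"age - (40 - GA) = {expected}; using computed value"
            )
            rec.adjusted_age = expected
    return rec


def write_session(rec: Recording, out_dir, manifest_name: str = "session.yaml") -> Path:
    """Write a recording as six sensor CSVs plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sensors = {}
    for sid, stream in rec.streams.items():
        fname = f"{sid}.csv"
        write_sensor_csv(stream, out_dir / fname)
        sensors[sid] = fname
    m = {
        "infant_id": rec.infant_id,
        "status": rec.status,
        "gestational_age_weeks": float(rec.gestational_age),
        "age_weeks": float(rec.age_at_test),
        "sensors": sensors,
        "calibration": {"start": float(rec.calibration_window[0]),
                        "end": float(rec.calibration_window[1])},
    }
    if rec.adjusted_age is not None:
        m["adjusted_age_weeks"] = float(rec.adjusted_age)
    path = out_dir / manifest_name
    with open(path, "w") as fh:
        yaml.safe_dump(m, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_recording(rec: Recording, segment_seconds: float = 60.0) -> list:
    """Slice the recording into consecutive fixed-length segments.

    The stationary calibration hold is excluded: segments start at the first
    sample at or after the calibration window's end.  A trailing remainder
    shorter than one segment is discarded.
    """
    if not segment_seconds > 0:
        raise ValueError("segment_seconds must be positive")
    fs = rec.sample_rate
    n_seg_samples = int(round(fs * segment_seconds))
    ref = next(iter(rec.streams.values()))
    start_idx = int(np.searchsorted(ref.t, rec.calibration_window[1]))
    usable = len(ref) - start_idx
    n_segments = usable // n_seg_samples
    if n_segments == 0:
        warnings.warn(
            f"usable span ({usable / fs:.1f}s) shorter than one "
            f"{segment_seconds:.0f}s segment; no segments emitted"
        )
        return []
    segments = []
    for m in range(n_segments):
        a = start_idx + m * n_seg_samples
        b = a + n_seg_samples
        segments.append(Segment(
            index=m,
            start_time=float(ref.t[a]),
            n_samples=n_seg_samples,
            sample_rate=fs,
            streams={sid: s.slice(a, b) for sid, s in rec.streams.items()},
        ))
    return segments


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(rows: Sequence[FeatureRow], path) -> None:
    """Write feature rows as CSV; undefined metrics become ``undef``.

    Floats are written at full (shortest round-trip) precision so the
    read-back table is bit-exact.
    """
    cols = FeatureRow.column_names()

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            v = float(v)
            return UNDEFINED_TOKEN if math.isnan(v) else repr(v)
        return v

    records = [{k: fmt(v) for k, v in r.to_dict().items()} for r in rows]
    df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, index=False)


def read_feature_table(path) -> list:
    """Read a feature-row CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, na_values=[UNDEFINED_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    unknown = set(df.columns) - set(FeatureRow.column_names())
    if unknown:
        raise IngestionError(f"unknown column {sorted(unknown)[0]!r}")
    missing = set(FeatureRow.column_names()) - set(df.columns)
    if missing:
        raise IngestionError(f"missing column {sorted(missing)[0]!r}")
    return [FeatureRow.from_dict(rec) for rec in df.to_dict("records")]


def feature_frame(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame (NaN marks undefined metrics)."""
    return pd.DataFrame([r.to_dict() for r in rows], columns=FeatureRow.column_names())
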