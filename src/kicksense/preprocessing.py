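"""Measurement-error correction and gross activity detection.

The MEMS sensors used for infant leg tracking suffer three error sources
that must be handled before any kinematic quantity is computed:

* a constant per-axis *bias* of gyroscope and accelerometer (gravity appears
  as part of the accelerometer bias in the supine rest orientation) — removed
  by subtracting the long-term average over the stationary calibration hold;
* *mechanical noise* — suppressed with a running median filter;
* slow *gyro drift* — removed with a zero-velocity update: during detected
  rest the angular rate is reset to zero, and the residual offset during each
  movement is interpolated from the flanking rest levels and subtracted.

Gross leg activity is detected by thresholding the smoothed maximum of the
three per-sensor gyro magnitudes of a leg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter as _nd_median, uniform_filter1d

from kicksense.io_model import Recording, SensorStream, SENSOR_IDS


@dataclass
class BiasEstimate:
    """Per-sensor gyro/accel offsets estimated over the calibration hold."""

    gyro_offset: dict  # sensor_id -> (3,) deg/s
    accel_offset: dict  # sensor_id -> (3,) g
    window_seconds: float

    def __post_init__(self) -> None:
        if self.window_seconds < 1.0:
            raise ValueError("bias estimation window must be >= 1 s")
        for store in (self.gyro_offset, self.accel_offset):
            for sid, v in store.items():
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"non-finite bias for {sid}")


@dataclass
class LegActivitySeries:
    """Binary activity labels for one leg over a sample range."""

    side: str
    values: np.ndarray  # uint8 in {0, 1}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.all((self.values == 0) | (self.values == 1)):
            raise ValueError("activity values must be binary")

    def __len__(self) -> int:
        return len(self.values)


def estimate_bias(rec: Recording) -> BiasEstimate:
    """Per-axis mean output over the stationary calibration window.

    The accelerometer offset includes the gravity component in the rest
    orientation, so subtracting it zeroes the rest-window specific force.
    """
    c0, c1 = rec.calibration_window
    if c1 - c0 < 1.0:
        raise ValueError(f"calibration window {c1 - c0:.2f}s shorter than 1 s")
    gyro_off, accel_off = {}, {}
    for sid in SENSOR_IDS:
        s = rec.streams[sid]
        mask = (s.t >= c0) & (s.t < c1)
        if not mask.any():
            raise ValueError(f"no samples in calibration window for {sid}")
        gyro_off[sid] = s.gyro[mask].mean(axis=0)
        accel_off[sid] = s.accel[mask].mean(axis=0)
    return BiasEstimate(gyro_offset=gyro_off, accel_offset=accel_off,
                        window_seconds=c1 - c0)


def apply_bias_correction(stream: SensorStream, bias: BiasEstimate) -> SensorStream:
    """Subtract the estimated offsets element-wise."""
    if stream.sensor_id not in bias.gyro_offset:
        raise KeyError(f"no bias estimate for {stream.sensor_id}")
    return stream.replace(
        gyro=stream.gyro - bias.gyro_offset[stream.sensor_id],
        accel=stream.accel - bias.accel_offset[stream.sensor_id],
    )


def median_filter(stream: SensorStream, window: int = 5) -> SensorStream:
    """Per-axis running median; edges use a window shrunk to the series.

    ``window`` must be odd and >= 3.  Default 5 samples (50 ms at 100 Hz)
    removes single-sample mechanical spikes without blunting kicks on the
    100 ms scale.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("median filter window must be odd and >= 3")
    return stream.replace(
        gyro=_running_median(stream.gyro, window),
        accel=_running_median(stream.accel, window),
    )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    out = _nd_median(x, size=(window, 1), mode="nearest")
    half = window // 2
    n = len(x)
    # shrink the window at the edges instead of replicating border samples
    for i in range(min(half, n)):
        out[i] = np.median(x[: i + half + 1], axis=0)
        out[n - 1 - i] = np.median(x[n - 1 - i - half:], axis=0)
    return out


def binary_runs(x: np.ndarray) -> list:
    """Half-open [start, stop) index ranges of the 1-runs of a binary series."""
    x = np.asarray(x).astype(bool)
    if len(x) == 0:
        return []
    d = np.diff(x.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if x[0]:
        starts.insert(0, 0)
    if x[-1]:
        stops.append(len(x))
    return list(zip(starts, stops))


def detect_activity(
    thigh_gyro: np.ndarray,
    shin_gyro: np.ndarray,
    foot_gyro: np.ndarray,
    sample_rate: float,
    side: str = "left",
    threshold_deg_s: float = 10.0,
    smooth_s: float = 0.1,
    min_event_s: float = 0.1,
    merge_gap_s: float = 0.1,
) -> LegActivitySeries:
    """Threshold-based gross activity detection for one leg.

    A sample is active iff the 0.1-s moving average of the maximum (over the
    leg's three sensors) gyro magnitude exceeds ``threshold_deg_s``.  Events
    shorter than ``min_event_s`` are removed, then gaps shorter than
    ``merge_gap_s`` are filled.
    """
    mags = np.maximum.reduce([
        np.linalg.norm(np.asarray(g, dtype=float), axis=1)
        for g in (thigh_gyro, shin_gyro, foot_gyro)
    ])
    w = max(1, int(round(smooth_s * sample_rate)))
    smoothed = uniform_filter1d(mags, size=w, mode="nearest")
    active = smoothed > threshold_deg_s

    min_event = int(round(min_event_s * sample_rate))
    for a, b in binary_runs(active):
        if b - a < min_event:
            active[a:b] = False
    merge_gap = int(round(merge_gap_s * sample_rate))
    for a, b in binary_runs(~active):
        if b - a < merge_gap and a > 0 and b < len(active):
            active[a:b] = True

    return LegActivitySeries(
        side=side,
        values=active.astype(np.uint8),
        params={"threshold_deg_s": threshold_deg_s, "smooth_s": smooth_s,
                "min_event_s": min_event_s, "merge_gap_s": merge_gap_s},
    )


def zero_velocity_update(gyro: np.ndarray, activity: LegActivitySeries,
                         guard_samples: int = 10,
                         dilate_samples: int = 25) -> np.ndarray:
    """Cancel gyro drift using detected rest.

    Within each inactive run the angular rate is set exactly to zero, so the
    integrated angle over any rest period is 0.  Within each active run the
    residual offset is estimated from the per-axis means of the flanking
    inactive runs, linearly interpolated across the run, and subtracted.

    Rest is treated conservatively: the activity mask is dilated by
    ``dilate_samples`` on each side before zeroing, so slow movement heads
    and tails below the detection threshold are offset-corrected rather
    than erased, and ``guard_samples`` are additionally trimmed from each
    end of a rest run before taking its mean.  Applying the update twice
    equals applying it once.
    """
    gyro = np.asarray(gyro, dtype=float)
    act = np.asarray(activity.values).astype(bool)
    if len(act) != len(gyro):
        raise ValueError("activity and gyro length mismatch")
    if dilate_samples > 0 and act.any():
        from scipy.ndimage import binary_dilation
        act = binary_dilation(act, iterations=dilate_samples)
    if act.all():
        warnings.warn("no inactive run; zero-velocity update skipped")
        return gyro.copy()
    out = gyro.copy()
    rest_runs = binary_runs(~act)

    def trimmed_mean(a, b):
        g = guard_samples if b - a > 3 * guard_samples else 0
        return gyro[a + g:b - g].mean(axis=0)

    rest_means = [trimmed_mean(a, b) for a, b in rest_runs]
    for a, b in rest_runs:
        out[a:b] = 0.0
    for a, b in binary_runs(act):
        prev = next((i for i in reversed(range(len(rest_runs)))
                     if rest_runs[i][1] <= a), None)
        nxt = next((i for i in range(len(rest_runs))
                    if rest_runs[i][0] >= b), None)
        if prev is None and nxt is None:  # unreachable: some rest exists
            continue
        lo = rest_means[prev] if prev is not None else rest_means[nxt]
        hi = rest_means[nxt] if nxt is not None else rest_means[prev]
        frac = (np.arange(a, b) - (a - 1)) / (b - a + 1)
        out[a:b] -= lo + frac[:, None] * (hi - lo)
    return out


def preprocess_recording(
    rec: Recording,
    median_window: int = 5,
    activity_threshold_deg_s: float = 10.0,
    activity_smooth_s: float = 0.1,
    activity_min_event_s: float = 0.1,
    activity_merge_gap_s: float = 0.1,
    apply_zvu: bool = True,
) -> tuple:
    """Full preprocessing chain: bias -> median filter -> activity -> ZVU.

    Returns ``(recording, activity)`` where ``activity`` maps side ->
    :class:`LegActivitySeries` over the whole session.
    """
    bias = estimate_bias(rec)
    streams = {
        sid: median_filter(apply_bias_correction(s, bias), median_window)
        for sid, s in rec.streams.items()
    }
    activity = {}
    for side in ("left", "right"):
        thigh, shin, foot = (streams[f"{side}_{seg}"] for seg in ("thigh", "shin", "foot"))
        activity[side] = detect_activity(
            thigh.gyro, shin.gyro, foot.gyro, rec.sample_rate, side=side,
            threshold_deg_s=activity_threshold_deg_s,
            smooth_s=activity_smooth_s,
            min_event_s=activity_min_event_s,
            merge_gap_s=activity_merge_gap_s,
        )
    if apply_zvu:
        for sid in list(streams):
            side = sid.split("_")[0]
            streams[sid] = streams[sid].replace(
                gyro=zero_velocity_update(streams[sid].gyro, activity[side])
            )
    out = Recording(
        infant_id=rec.infant_id, status=rec.status,
        gestational_age=rec.gestational_age, age_at_test=rec.age_at_test,
        streams=streams, calibration_window=rec.calibration_window,
        adjusted_age=rec.adjusted_age,
    )
    return out, activity
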