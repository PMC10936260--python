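"""Ground-truth-labeled synthetic kicking sessions and cohorts.

The generator emulates the structure of supine-infant kicking data as seen
by a six-sensor lower-limb IMU suit: kicks arrive in bouts separated by
rest, each bout is bilateral or unilateral, and every bout realizes one
kick cycle per involved leg — a smooth raised-cosine angle pulse per DOF
(flexion to a programmed excursion and back, zero rate at the boundaries).
Sensor streams are synthesized by stacking joint angular rates down the
kinematic chain (thigh = hip, shin = thigh + knee, foot = shin + ankle) on
anatomically aligned axes, adding per-axis sensor bias, a slow gyro drift
ramp and white noise, and prepending a stationary calibration hold.  The
foot accelerometer carries a tangential-acceleration proxy (scaled second
derivative of the summed flexion angles) on top of gravity.

Every simulated session comes with a :class:`GroundTruth` holding the event
list, from which the true value of each segment-level kinematic feature is
computable — the central surface for end-to-end recovery tests.

Default condition choices: 100 Hz sampling (the acquisition rate of the
suit), 5-minute sessions with a 5-s hold, ~10 bouts/min of mean duration
2 s (activity fraction near 0.35, mid-range for supine infants), hip/knee
flexion excursions of 25/20 degrees (comfortably above the 11.5-degree
kick-cycle threshold), and sensor error magnitudes typical of consumer
MEMS IMUs (0.5 deg/s white noise, ~1 deg/s bias, 0.5 deg/s-per-minute
drift ramp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from kicksense.io_model import DOFS, Recording, SensorStream, SessionSummary

_G = 9.80665
_LIMB_M = 0.1  # effective lever arm of the foot sensor, meters

DEFAULT_AMPLITUDES = {
    "hip_flex": 25.0, "hip_abd": 8.0, "hip_rot": 6.0,
    "knee_flex": 20.0, "ankle_flex": 12.0, "ankle_inv": 5.0,
}

#: sensor-frame axis of each DOF used for synthesis (x flexion,
#: y abduction/inversion, z rotation); matches kinematics.default_axes
_DOF_AXIS = {"hip_flex": 0, "hip_abd": 1, "hip_rot": 2,
             "knee_flex": 0, "ankle_flex": 0, "ankle_inv": 1}


@dataclass
class SimConfig:
    """Generating conditions of one synthetic kicking session."""

    seed: int = 0
    session_s: float = 300.0
    sample_rate: float = 100.0
    calibration_s: float = 5.0
    # bout process
    bout_rate_per_min: float = 10.0
    duration_mean_s: float = 2.0
    duration_sigma: float = 0.4  # lognormal shape
    min_gap_s: float = 0.4
    coord_probs: dict = field(default_factory=lambda: {"UL": 0.25, "UR": 0.25, "B": 0.5})
    # per-DOF pulse excursions (deg) and relative jitter
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    amplitude_jitter: float = 0.15
    # intra-kick timing: fraction of a stroke spent flexing, and the
    # proximal-to-distal onset lags of knee and ankle (fractions of the
    # bout duration)
    flex_frac: float = 0.4
    knee_lag_frac: float = 0.1
    ankle_lag_frac: float = 0.18
    # sensor error model
    gyro_noise_sigma: float = 0.5  # deg/s
    accel_noise_sigma: float = 0.02  # g
    gyro_bias_sigma: float = 1.0  # deg/s
    accel_bias_sigma: float = 0.05  # g
    drift_deg_s_per_min: float = 0.5
    # session metadata
    infant_id: str = "sim000"
    status: str = "term"
    gestational_age: float = 39.0
    age_weeks: float = 20.0

    def __post_init__(self) -> None:
        total = sum(self.coord_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"coordination probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.coord_probs.values()):
            raise ValueError("coordination probabilities must be >= 0")
        for name in ("gyro_noise_sigma", "accel_noise_sigma",
                     "gyro_bias_sigma", "accel_bias_sigma",
                     "drift_deg_s_per_min", "amplitude_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.duration_mean_s <= 0 or self.duration_sigma < 0:
            raise ValueError("invalid duration distribution parameters")
        if not 0 < self.flex_frac < 1:
            raise ValueError("flex_frac must be in (0, 1)")
        for name in ("knee_lag_frac", "ankle_lag_frac"):
            if not 0 <= getattr(self, name) < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")


@dataclass
class SimEvent:
    """One kicking bout: interval, coordination label, per-leg excursions.

    ``amplitudes`` are signed: the flexion DOFs are always positive, the
    secondary DOFs (abduction, rotation, inversion) take either sign.
    ``windows`` gives each DOF's (start, width) as fractions of the bout.
    """

    start: float  # s, session clock
    duration: float  # s
    label: str  # "UL" | "UR" | "B"
    amplitudes: dict  # side -> dof -> signed excursion deg
    windows: dict = field(default_factory=dict)  # side -> dof -> (start_frac, width_frac)

    @property
    def sides(self) -> tuple:
        return {"UL": ("left",), "UR": ("right",), "B": ("left", "right")}[self.label]

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class GroundTruth:
    """Event-level truth for one simulated session."""

    config: SimConfig
    events: list

    def activity(self, side: str, n: int, sample_rate: float) -> np.ndarray:
        """Truth per-sample activity labels for one leg."""
        t = np.arange(n) / sample_rate
        act = np.zeros(n, dtype=np.uint8)
        for ev in self.events:
            if side in ev.sides:
                act[(t >= ev.start) & (t < ev.end)] = 1
        return act

    def predominant_leg(self) -> str:
        left = sum(ev.duration for ev in self.events if "left" in ev.sides)
        right = sum(ev.duration for ev in self.events if "right" in ev.sides)
        return "left" if left > right else "right"

    def segment_features(self, start_s: float, end_s: float) -> dict:
        """True feature values of one segment, from the event list alone."""
        fs = self.config.sample_rate
        n = int(round((end_s - start_s) * fs))
        t = start_s + np.arange(n) / fs
        s_l = np.zeros(n, dtype=bool)
        s_r = np.zeros(n, dtype=bool)
        for ev in self.events:
            mask = (t >= ev.start) & (t < ev.end)
            if "left" in ev.sides:
                s_l |= mask
            if "right" in ev.sides:
                s_r |= mask
        s = s_l | s_r
        n_ul = int(np.count_nonzero(s_l & ~s_r))
        n_ur = int(np.count_nonzero(s_r & ~s_l))
        n_b = int(np.count_nonzero(s_l & s_r))
        out = {
            "F_act": np.count_nonzero(s) / n,
            "F_rest": np.count_nonzero(~s) / n,
            "F_B": n_b / n, "F_UL": n_ul / n, "F_UR": n_ur / n,
            "F_UP": max(n_ul, n_ur) / n,
        }
        d_kick, d_rest = _run_durations(s, fs)
        out["D_avg_kick"] = float(np.mean(d_kick)) if d_kick else 0.0
        out["D_max_kick"] = float(np.max(d_kick)) if d_kick else 0.0
        out["D_avg_rest"] = float(np.mean(d_rest)) if d_rest else 0.0
        out["D_max_rest"] = float(np.max(d_rest)) if d_rest else 0.0
        pred = self.predominant_leg()
        inside = [ev for ev in self.events
                  if pred in ev.sides and ev.start >= start_s and ev.end <= end_s]
        for dof in DOFS:
            amps = [abs(ev.amplitudes[pred][dof]) for ev in inside]
            mx = max(amps) if amps else 0.0
            # each pulse returns to baseline, so both directions see the
            # full excursion
            out[f"Emax_pos_{dof}"] = mx
            out[f"Emax_neg_{dof}"] = mx
        out["K"] = sum(
            1 for ev in inside
            if max(ev.amplitudes[pred]["hip_flex"],
                   ev.amplitudes[pred]["knee_flex"]) > 11.5
            and ev.duration / 2 >= 0.05
        )
        cc = (_truth_interjoint(self.config.flex_frac,
                                self.config.knee_lag_frac,
                                self.config.ankle_lag_frac)
              if inside else {"HK": float("nan"), "HA": float("nan"),
                              "KA": float("nan")})
        out["C_HK"], out["C_HA"], out["C_KA"] = cc["HK"], cc["HA"], cc["KA"]
        out["predominant_leg"] = pred
        return out


def _run_durations(binary: np.ndarray, fs: float) -> tuple:
    from kicksense.preprocessing import binary_runs
    dt = 1.0 / fs
    kick = [(b - a) * dt for a, b in binary_runs(binary)]
    rest = [(b - a) * dt for a, b in binary_runs(~binary)]
    return kick, rest


_SECONDARY_DOFS = ("hip_abd", "hip_rot", "ankle_inv")


def _stroke_shape(m: int, flex_frac: float) -> np.ndarray:
    """Unit-excursion flexion-then-extension rate shape over m samples.

    The angle rises by 1 over the first ``flex_frac`` of the window (half
    cosine) and falls back to 0 over the remainder, so the flexion stroke
    is faster than the extension stroke.  Rates are sampled at interval
    midpoints: the left-Riemann sum of each stroke is 1 to O(1/m^2).
    Returned rates are per unit window duration (scale by 1/duration).
    """
    u = (np.arange(m) + 0.5) / m
    f = flex_frac
    up = np.pi / (2 * f) * np.sin(np.pi * u / f)
    down = -np.pi / (2 * (1 - f)) * np.sin(np.pi * (u - f) / (1 - f))
    return np.where(u < f, up, down)


def _dof_windows(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Per-DOF (start, width) window fractions for one event.

    Flexion DOFs follow proximal-to-distal sequencing (knee and ankle lag
    the hip); secondary DOFs occupy a random sub-window.
    """
    win = {
        "hip_flex": (0.0, 1.0),
        "knee_flex": (cfg.knee_lag_frac, 1.0 - cfg.knee_lag_frac),
        "ankle_flex": (cfg.ankle_lag_frac, 1.0 - cfg.ankle_lag_frac),
    }
    for dof in _SECONDARY_DOFS:
        win[dof] = (float(rng.uniform(0.0, 0.35)), 0.55)
    return win


def _draw_events(cfg: SimConfig, rng: np.random.Generator) -> list:
    total = cfg.calibration_s + cfg.session_s
    labels = sorted(cfg.coord_probs)
    probs = np.array([cfg.coord_probs[k] for k in labels])
    mu = math.log(cfg.duration_mean_s) - cfg.duration_sigma ** 2 / 2
    rate = cfg.bout_rate_per_min / 60.0
    events = []
    cur = cfg.calibration_s + 0.5
    while rate > 0:
        cur += rng.exponential(1.0 / rate)
        dur = float(np.clip(rng.lognormal(mu, cfg.duration_sigma), 0.4, 6.0))
        if cur + dur > total - 0.5:
            break
        label = str(rng.choice(labels, p=probs))
        amps, windows = {}, {}
        for side in ("left", "right"):
            side_amps = {}
            for dof, a in cfg.amplitudes.items():
                v = max(1.0, a * (1 + cfg.amplitude_jitter * rng.standard_normal()))
                if dof in _SECONDARY_DOFS and rng.random() < 0.5:
                    v = -v
                side_amps[dof] = v
            amps[side] = side_amps
            windows[side] = _dof_windows(cfg, rng)
        events.append(SimEvent(start=cur, duration=dur, label=label,
                               amplitudes=amps, windows=windows))
        cur += dur + cfg.min_gap_s
    return events


def _pulse_rates(n: int, fs: float, events: list, side: str,
                 flex_frac: float) -> dict:
    """Per-DOF angular-rate series (deg/s) of one leg from its events."""
    rates = {dof: np.zeros(n) for dof in DOFS}
    for ev in events:
        if side not in ev.sides:
            continue
        for dof, amp in ev.amplitudes[side].items():
            w0, wf = ev.windows[side][dof]
            t0 = ev.start + w0 * ev.duration
            dur_w = wf * ev.duration
            i0 = int(round(t0 * fs))
            i1 = min(n, int(round((t0 + dur_w) * fs)))
            m = i1 - i0
            if m < 2:
                continue
            rates[dof][i0:i1] += amp * _stroke_shape(m, flex_frac) / dur_w
    return rates


def _truth_interjoint(flex_frac: float, knee_lag: float, ankle_lag: float,
                      _cache={}) -> dict:
    """True inter-joint angle correlations implied by the pulse timing.

    Computed on a fine canonical grid (correlations are invariant to bout
    duration and amplitude): joint angles are re-zeroed at the start of
    each window where both hip and knee rates share a sign, and the sample
    correlation of each joint pair is averaged over the flexion and
    extension windows, honoring the ankle-in-phase rule.
    """
    key = (round(flex_frac, 6), round(knee_lag, 6), round(ankle_lag, 6))
    if key in _cache:
        return _cache[key]
    n = 4000
    series = {}
    for name, lag in (("hip", 0.0), ("knee", knee_lag), ("ankle", ankle_lag)):
        r = np.zeros(n)
        i0 = int(round(lag * n))
        m = n - i0
        r[i0:] = _stroke_shape(m, flex_frac) / (1.0 - lag)
        series[name] = r
    hip, knee, ankle = series["hip"], series["knee"], series["ankle"]
    rho = {"HK": [], "HA": [], "KA": []}
    for sign in (1, -1):
        mask = (np.sign(hip) == sign) & (np.sign(knee) == sign)
        idx = np.nonzero(mask)[0]
        if idx.size < 2:
            continue
        a, b = idx[0], idx[-1] + 1
        ang = {j: np.cumsum(series_j[a:b]) for j, series_j in series.items()}
        ankle_ok = np.mean(np.sign(ankle[a:b]) == sign) > 0.5
        pairs = [("HK", "hip", "knee")]
        if ankle_ok:
            pairs += [("HA", "hip", "ankle"), ("KA", "knee", "ankle")]
        for pair, j1, j2 in pairs:
            if np.std(ang[j1]) > 1e-12 and np.std(ang[j2]) > 1e-12:
                rho[pair].append(float(np.corrcoef(ang[j1], ang[j2])[0, 1]))
    out = {p: (float(np.mean(v)) if v else float("nan")) for p, v in rho.items()}
    _cache[key] = out
    return out


def simulate_session(cfg: SimConfig) -> tuple:
    """Generate one six-sensor recording plus its ground truth.

    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    total = cfg.calibration_s + cfg.session_s
    n = int(round(total * fs))
    t = np.arange(n) / fs

    events = _draw_events(cfg, rng)
    truth = GroundTruth(config=cfg, events=events)

    streams = {}
    for side in ("left", "right"):
        rates = _pulse_rates(n, fs, events, side, cfg.flex_frac)
        thigh = np.zeros((n, 3))
        for dof in ("hip_flex", "hip_abd", "hip_rot"):
            thigh[:, _DOF_AXIS[dof]] += rates[dof]
        shin = thigh.copy()
        shin[:, _DOF_AXIS["knee_flex"]] += rates["knee_flex"]
        foot = shin.copy()
        foot[:, _DOF_AXIS["ankle_flex"]] += rates["ankle_flex"]
        foot[:, _DOF_AXIS["ankle_inv"]] += rates["ankle_inv"]

        # foot specific force: tangential proxy from summed flexion angles
        total_rate = rates["hip_flex"] + rates["knee_flex"] + rates["ankle_flex"]
        ang_accel = np.gradient(total_rate, 1.0 / fs)  # deg/s^2
        a_tan = _LIMB_M * np.deg2rad(ang_accel) / _G  # g

        for seg_name, gyro in (("thigh", thigh), ("shin", shin), ("foot", foot)):
            gyro = gyro.copy()
            bias = rng.normal(0.0, cfg.gyro_bias_sigma, 3)
            drift = rng.uniform(-1, 1, 3) * cfg.drift_deg_s_per_min / 60.0
            gyro += bias + drift * t[:, None]
            gyro += rng.normal(0.0, cfg.gyro_noise_sigma, (n, 3))

            accel = np.zeros((n, 3))
            accel[:, 2] = 1.0  # gravity in the supine rest orientation
            if seg_name == "foot":
                accel[:, 0] += a_tan
            accel += rng.normal(0.0, cfg.accel_bias_sigma, 3)
            accel += rng.normal(0.0, cfg.accel_noise_sigma, (n, 3))

            sid = f"{side}_{seg_name}"
            streams[sid] = SensorStream(sensor_id=sid, sample_rate=fs,
                                        t=t.copy(), gyro=gyro, accel=accel)

    rec = Recording(
        infant_id=cfg.infant_id, status=cfg.status,
        gestational_age=cfg.gestational_age, age_at_test=cfg.age_weeks,
        streams=streams, calibration_window=(0.0, cfg.calibration_s),
    )
    return rec, truth


def truth_session_summary(truth: GroundTruth,
                          segment_seconds: float = 60.0) -> SessionSummary:
    """Session summary computed from ground truth (no sensor pipeline)."""
    cfg = truth.config
    n_seg = int(cfg.session_s // segment_seconds)
    per_seg = [
        truth.segment_features(cfg.calibration_s + m * segment_seconds,
                               cfg.calibration_s + (m + 1) * segment_seconds)
        for m in range(n_seg)
    ]
    numeric = [k for k in per_seg[0] if k != "predominant_leg"]
    medians = {k: float(np.median([d[k] for d in per_seg])) for k in numeric}
    return SessionSummary(infant_id=cfg.infant_id, age_at_test=cfg.age_weeks,
                          features=medians, n_segments_retained=n_seg)


def simulate_cohort(ages, trends=None, seed: int = 0, base: SimConfig = None,
                    with_sensors: bool = True) -> list:
    """Simulate one session per age with age-dependent generating conditions.

    ``trends`` maps a SimConfig field (or ``"amplitude_scale"``, which
    multiplies every per-DOF excursion) to a callable of age in weeks.
    Returns a list of ``(recording_or_None, ground_truth)`` pairs; with
    ``with_sensors=False`` only the event process is realized, for cheap
    cohort-level studies of the screening stage.
    """
    trends = trends or {}
    base = base or SimConfig()
    out = []
    for i, age in enumerate(ages):
        cfg = replace(base,
                      seed=(seed * 100003 + i) % (2 ** 31 - 1),
                      infant_id=f"sim{i:03d}",
                      age_weeks=float(age),
                      amplitudes=dict(base.amplitudes),
                      coord_probs=dict(base.coord_probs))
        for key, fn in trends.items():
            if key == "amplitude_scale":
                s = float(fn(age))
                cfg.amplitudes = {d: a * s for d, a in cfg.amplitudes.items()}
            else:
                setattr(cfg, key, float(fn(age)))
        if with_sensors:
            rec, truth = simulate_session(cfg)
        else:
            rng = np.random.default_rng(cfg.seed)
            rec, truth = None, GroundTruth(config=cfg,
                                           events=_draw_events(cfg, rng))
        out.append((rec, truth))
    return out
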