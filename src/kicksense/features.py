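"""Segment-level kinematic metrics and session aggregation.

Implements the full feature set describing spontaneous kicking in a
one-minute segment:

* frequency metrics — fractions of samples spent active, resting, and in
  each coordination pattern (bilateral, unilateral left/right/predominant);
* duration metrics — mean and maximum durations of movement and rest runs;
* acceleration metrics — mean and peak specific-force magnitude of the
  predominant leg's foot sensor during that leg's activity;
* maximum joint excursions — per DOF and direction, predominant leg;
* inter-joint coordination — mean zero-lag correlation of paired joint
  angles (hip-knee, hip-ankle, knee-ankle) over kick-cycle flexion and
  extension windows, with each angle re-zeroed at the window start.

Session aggregation excludes outlier segments (activity or rest fraction
greater than 0.9) and takes the per-feature median across retained
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from kicksense.io_model import DOFS, FeatureRow, Segment, SessionSummary
from kicksense.kinematics import (
    JointAxisSet,
    compute_leg_dofs,
    leg_excursions,
    max_excursions,
)
from kicksense.coordination import (
    KickCycleSet,
    combine_activity,
    coordination_vector,
    detect_kick_cycles,
)
from kicksense.preprocessing import binary_runs, detect_activity

#: numeric features carried into session summaries and age-trend screening
FEATURE_NAMES = (
    "F_act", "F_rest", "F_B", "F_UL", "F_UR", "F_UP",
    "D_avg_kick", "D_max_kick", "D_avg_rest", "D_max_rest",
    "A_avg", "A_peak", "C_HK", "C_HA", "C_KA",
    *(f"Emax_pos_{d}" for d in DOFS),
    *(f"Emax_neg_{d}" for d in DOFS),
)


@dataclass
class DurationEvents:
    """Movement and rest runs of one segment, in seconds."""

    movement_runs: list  # (start_s, end_s)
    rest_runs: list
    D_kick: list  # durations of movement runs, s
    D_rest: list


@dataclass
class InterJointResult:
    """Per-pair mean kick-cycle angle correlations (NaN when undefined)."""

    C_avg: dict  # pair -> float
    rho: dict = field(default_factory=dict)  # pair -> list of per-window rho


def frequency_features(S, V, N: int | None = None) -> dict:
    """Activity/coordination frequencies as fractions of segment samples."""
    S = np.asarray(S)
    V = np.asarray(V)
    if N is None:
        N = len(S)
    if N == 0:
        raise ValueError("empty segment")
    if len(S) != N or len(V) != N:
        raise ValueError("S and V must have N samples")
    F_UL = float(np.count_nonzero(V == 1)) / N
    F_UR = float(np.count_nonzero(V == 2)) / N
    F_B = float(np.count_nonzero(V == 3)) / N
    F_act = float(np.count_nonzero(S)) / N
    return {
        "F_act": F_act,
        "F_rest": float(np.count_nonzero(S == 0)) / N,
        "F_B": F_B,
        "F_UL": F_UL,
        "F_UR": F_UR,
        "F_UP": max(F_UL, F_UR),
    }


def duration_features(S, sample_rate: float) -> tuple:
    """Mean/max durations of movement and rest runs; 0 when a kind is absent.

    Runs touching the segment edges are counted at their observed length.
    Returns ``(metrics, DurationEvents)``.
    """
    S = np.asarray(S).astype(bool)
    dt = 1.0 / sample_rate
    move = [(a * dt, b * dt) for a, b in binary_runs(S)]
    rest = [(a * dt, b * dt) for a, b in binary_runs(~S)]
    d_kick = [b - a for a, b in move]
    d_rest = [b - a for a, b in rest]
    metrics = {
        "D_avg_kick": float(np.mean(d_kick)) if d_kick else 0.0,
        "D_max_kick": float(np.max(d_kick)) if d_kick else 0.0,
        "D_avg_rest": float(np.mean(d_rest)) if d_rest else 0.0,
        "D_max_rest": float(np.max(d_rest)) if d_rest else 0.0,
    }
    return metrics, DurationEvents(move, rest, d_kick, d_rest)


def acceleration_features(foot_accel, S_pred) -> dict:
    """Mean and peak foot specific-force magnitude over active samples.

    ``S_pred`` is the predominant leg's activity series.  With no active
    samples both metrics are undefined (NaN).
    """
    accel = np.asarray(foot_accel, dtype=float)
    active = np.asarray(S_pred).astype(bool)
    if len(accel) != len(active):
        raise ValueError("accel and activity length mismatch")
    if not active.any():
        return {"A_avg": float("nan"), "A_peak": float("nan")}
    mags = np.linalg.norm(accel[active], axis=1)
    return {"A_avg": float(mags.mean()), "A_peak": float(mags.max())}


_PAIRS = {"HK": ("hip_flex", "knee_flex"),
          "HA": ("hip_flex", "ankle_flex"),
          "KA": ("knee_flex", "ankle_flex")}


def interjoint_coordination(
    rates: dict, cycles: KickCycleSet, sample_rate: float
) -> InterJointResult:
    """Mean zero-lag correlation of paired joint angles over cycle windows.

    For every full-flexion and full-extension window the hip, knee and
    ankle flexion angles are re-zeroed at the window start (integrated from
    the angular rates within the window) and the sample correlation of each
    pair is stored.  Hip-ankle and knee-ankle use only windows whose
    ankle-in-phase flag is set.  Windows with a constant angle are skipped.
    """
    rho = {pair: [] for pair in _PAIRS}
    for cycle in cycles.cycles:
        for (a, b), ankle_ok in (
            (cycle.flexion, cycle.flex_ankle_in_phase),
            (cycle.extension, cycle.ext_ankle_in_phase),
        ):
            angles = {j: np.cumsum(np.asarray(rates[j], dtype=float)[a:b]) / sample_rate
                      for j in ("hip_flex", "knee_flex", "ankle_flex")}
            for pair, (j1, j2) in _PAIRS.items():
                if pair in ("HA", "KA") and not ankle_ok:
                    continue
                x, y = angles[j1], angles[j2]
                if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                    warnings.warn(
                        f"constant angle in window [{a},{b}); {pair} skipped")
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                rho[pair].append(min(1.0, max(-1.0, r)))
    c_avg = {pair: (float(np.mean(v)) if v else float("nan"))
             for pair, v in rho.items()}
    return InterJointResult(C_avg=c_avg, rho=rho)


def extract_features(
    segment: Segment,
    axes: JointAxisSet,
    predominant: str,
    config=None,
) -> FeatureRow:
    """Run the full per-segment chain and assemble a validated FeatureRow.

    ``axes`` are the predominant leg's joint axes (estimated once per
    session); ``config`` is a :class:`kicksense.config.PipelineConfig`
    (defaults are used when omitted).
    """
    from kicksense.config import PipelineConfig

    cfg = config or PipelineConfig()
    fs = segment.sample_rate
    try:
        act = {}
        for side in ("left", "right"):
            thigh, shin, foot = segment.leg_streams(side)
            act[side] = detect_activity(
                thigh.gyro, shin.gyro, foot.gyro, fs, side=side,
                threshold_deg_s=cfg.preprocess.activity_threshold_deg_s,
                smooth_s=cfg.preprocess.activity_smooth_s,
                min_event_s=cfg.preprocess.activity_min_event_s,
                merge_gap_s=cfg.preprocess.activity_merge_gap_s,
            ).values
        av = combine_activity(act["left"], act["right"])
        cv = coordination_vector(act["left"], act["right"])
        freq = frequency_features(av.S, cv.V, segment.n_samples)
        dur, _ = duration_features(av.S, fs)

        thigh, shin, foot = segment.leg_streams(predominant)
        accel = acceleration_features(foot.accel, act[predominant])

        series = compute_leg_dofs(
            thigh.gyro, shin.gyro, foot.gyro, axes, fs,
            rest_deg=cfg.phase.rest_deg, rest_window_s=cfg.phase.rest_window_s,
        )
        excursions = leg_excursions(series, fs)
        emax_pos, emax_neg = {}, {}
        for dof in DOFS:
            ep, en = max_excursions(excursions[dof])
            emax_pos[dof], emax_neg[dof] = ep, en

        cycles = detect_kick_cycles(
            series["hip_flex"], series["knee_flex"], series["ankle_flex"],
            min_flex_s=cfg.kick_cycle.min_flex_ms / 1000.0,
            min_excursion_deg=cfg.kick_cycle.min_excursion_deg,
        )
        rates = {d: series[d].rate for d in ("hip_flex", "knee_flex", "ankle_flex")}
        ijc = interjoint_coordination(rates, cycles, fs)

        return FeatureRow(
            segment_index=segment.index,
            **freq, **dur, **accel,
            C_HK=ijc.C_avg["HK"], C_HA=ijc.C_avg["HA"], C_KA=ijc.C_avg["KA"],
            Emax_pos=emax_pos, Emax_neg=emax_neg,
            predominant_leg=predominant, K=cycles.K,
        )
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed in segment "
                           f"{segment.index}: {exc}") from exc


def segment_outlier_filter(rows, max_fraction: float = 0.9) -> list:
    """Drop segments with F_act or F_rest strictly greater than 0.9."""
    return [r for r in rows
            if not (r.F_act > max_fraction or r.F_rest > max_fraction)]


def session_medians(rows, infant_id: str, age_at_test: float) -> SessionSummary:
    """Per-feature median over retained rows, masking undefined entries.

    A feature undefined in every retained row stays undefined (NaN).  An
    even number of defined entries yields the mean of the middle two.
    """
    if not rows:
        raise ValueError("no retained segments to summarize")
    medians = {}
    for name in FEATURE_NAMES:
        vals = np.array([_row_value(r, name) for r in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        medians[name] = float(np.median(vals)) if len(vals) else float("nan")
    k = np.array([r.K for r in rows], dtype=float)
    medians["K"] = float(np.median(k))
    return SessionSummary(infant_id=infant_id, age_at_test=age_at_test,
                          features=medians, n_segments_retained=len(rows))


def _row_value(row: FeatureRow, name: str) -> float:
    if name.startswith("Emax_pos_"):
        return row.Emax_pos.get(name[len("Emax_pos_"):], 0.0)
    if name.startswith("Emax_neg_"):
        return row.Emax_neg.get(name[len("Emax_neg_"):], 0.0)
    return getattr(row, name)


def extract_session(recording, config=None) -> tuple:
    """End-to-end extraction for one session.

    Preprocesses the recording, determines the predominant leg, estimates
    that leg's joint axes from the whole session, segments the usable span
    and extracts one FeatureRow per segment.  Returns ``(rows, meta)``.
    """
    from kicksense.config import PipelineConfig
    from kicksense.io_model import segment_recording
    from kicksense.kinematics import estimate_joint_axes
    from kicksense.preprocessing import preprocess_recording
    from kicksense.coordination import predominant_leg

    cfg = config or PipelineConfig()
    pp = cfg.preprocess
    clean, activity = preprocess_recording(
        recording,
        median_window=pp.median_window,
        activity_threshold_deg_s=pp.activity_threshold_deg_s,
        activity_smooth_s=pp.activity_smooth_s,
        activity_min_event_s=pp.activity_min_event_s,
        activity_merge_gap_s=pp.activity_merge_gap_s,
    )
    pred = predominant_leg(activity["left"].values, activity["right"].values)
    thigh, shin, foot = clean.leg_streams(pred)
    if activity[pred].values.any():
        axes = estimate_joint_axes(thigh.gyro, shin.gyro, foot.gyro,
                                   activity[pred].values)
    else:  # all-rest session: fall back to anatomically aligned axes
        from kicksense.kinematics import default_axes
        axes = default_axes()
    segments = segment_recording(clean, cfg.segmentation.segment_seconds)
    rows = [extract_features(seg, axes, pred, cfg) for seg in segments]
    meta = {
        "infant_id": recording.infant_id,
        "age_weeks": recording.age_at_test,
        "predominant_leg": pred,
        "n_segments": len(rows),
    }
    return rows, meta
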