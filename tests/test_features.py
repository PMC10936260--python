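"""Segment-level metrics and session aggregation."""

import numpy as np
import pytest

from kicksense.coordination import KickCycle, KickCycleSet
from kicksense.features import (
    acceleration_features,
    duration_features,
    extract_features,
    frequency_features,
    interjoint_coordination,
    segment_outlier_filter,
    session_medians,
)
from kicksense.io_model import Segment, SensorStream
from kicksense.kinematics import default_axes
from tests.conftest import random_feature_row

FS = 100.0


class TestFrequency:
    def test_hand_counted_example(self):
        v = np.zeros(100, dtype=int)
        v[:10] = 1   # unilateral left
        v[10:15] = 2  # unilateral right
        v[15:30] = 3  # bilateral
        s = (v > 0).astype(int)
        f = frequency_features(s, v, 100)
        assert f == {"F_act": 0.30, "F_rest": 0.70, "F_B": 0.15,
                     "F_UL": 0.10, "F_UR": 0.05, "F_UP": 0.10}

    def test_all_rest(self):
        f = frequency_features(np.zeros(50), np.zeros(50))
        assert f["F_act"] == 0.0 and f["F_rest"] == 1.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            frequency_features([], [], 0)

    def test_partition_identities_random(self):
        rng = np.random.default_rng(40)
        for _ in range(500):
            sl = (rng.random(600) < rng.random()).astype(int)
            sr = (rng.random(600) < rng.random()).astype(int)
            v = sl + 2 * sr
            s = (v > 0).astype(int)
            f = frequency_features(s, v)
            assert f["F_B"] + f["F_UL"] + f["F_UR"] == pytest.approx(f["F_act"])
            assert f["F_act"] + f["F_rest"] == pytest.approx(1.0)


class TestDuration:
    def test_hand_counted_example(self):
        m, ev = duration_features([0, 1, 1, 1, 0, 1, 0], sample_rate=1.0)
        assert ev.D_kick == [3.0, 1.0]
        assert ev.D_rest == [1.0, 1.0, 1.0]
        assert m == {"D_avg_kick": 2.0, "D_max_kick": 3.0,
                     "D_avg_rest": 1.0, "D_max_rest": 1.0}

    def test_all_active_segment(self):
        m, _ = duration_features(np.ones(60), sample_rate=1.0)
        assert m["D_avg_kick"] == m["D_max_kick"] == 60.0
        assert m["D_avg_rest"] == m["D_max_rest"] == 0.0

    def test_runs_tile_segment(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            s = (rng.random(6000) < 0.3).astype(int)
            _, ev = duration_features(s, FS)
            assert sum(ev.D_kick) + sum(ev.D_rest) == pytest.approx(60.0)

    def test_simulator_bout_durations(self, sim_session, extracted):
        cfg, _, truth = sim_session
        rows, _, _ = extracted
        for row in rows:
            start = cfg.calibration_s + row.segment_index * 60.0
            tf = truth.segment_features(start, start + 60.0)
            if tf["D_avg_kick"] > 0:
                assert row.D_avg_kick == pytest.approx(tf["D_avg_kick"],
                                                       rel=0.15)


class TestAcceleration:
    def test_constant_magnitude(self):
        accel = np.tile([0.5, 0.0, 0.0], (100, 1))
        f = acceleration_features(accel, np.ones(100))
        assert f == {"A_avg": 0.5, "A_peak": 0.5}

    def test_inactive_samples_excluded(self):
        accel = np.zeros((4, 3))
        accel[:, 0] = [1.0, 3.0, 0.2, 0.2]
        f = acceleration_features(accel, [1, 1, 0, 0])
        assert f == {"A_avg": 2.0, "A_peak": 3.0}

    def test_no_activity_undefined(self):
        f = acceleration_features(np.ones((10, 3)), np.zeros(10))
        assert np.isnan(f["A_avg"]) and np.isnan(f["A_peak"])

    def test_matches_masked_oracle(self):
        rng = np.random.default_rng(42)
        accel = rng.normal(0, 1, (500, 3))
        s = (rng.random(500) < 0.5).astype(int)
        f = acceleration_features(accel, s)
        mags = [np.sqrt(a @ a) for a, si in zip(accel, s) if si]
        assert f["A_avg"] == pytest.approx(np.mean(mags), rel=1e-12)
        assert f["A_peak"] == pytest.approx(np.max(mags), rel=1e-12)


def _cycles(n, window=50, gap=100):
    cycles = []
    for k in range(n):
        a = k * (2 * window + 2 * gap)
        cycles.append(KickCycle(flexion=(a, a + window),
                                extension=(a + window + gap,
                                           a + 2 * window + gap),
                                flex_ankle_in_phase=True,
                                ext_ankle_in_phase=True,
                                hip_excursion=20.0, knee_excursion=20.0))
    return KickCycleSet(cycles=cycles)


class TestInterjoint:
    def test_proportional_angles_perfectly_correlated(self):
        rng = np.random.default_rng(43)
        cycles = _cycles(5)
        n = cycles.cycles[-1].extension[1] + 10
        hip = rng.normal(0, 20, n)
        rates = {"hip_flex": hip, "knee_flex": 2 * hip, "ankle_flex": hip}
        res = interjoint_coordination(rates, cycles, FS)
        assert res.C_avg["HK"] == pytest.approx(1.0)

    def test_opposed_angles_anticorrelated(self):
        rng = np.random.default_rng(44)
        cycles = _cycles(5)
        n = cycles.cycles[-1].extension[1] + 10
        hip = rng.normal(0, 20, n)
        rates = {"hip_flex": hip, "knee_flex": -hip, "ankle_flex": hip}
        res = interjoint_coordination(rates, cycles, FS)
        assert res.C_avg["HK"] == pytest.approx(-1.0)

    def test_no_cycles_undefined(self):
        rates = {k: np.zeros(100) for k in ("hip_flex", "knee_flex", "ankle_flex")}
        res = interjoint_coordination(rates, KickCycleSet(cycles=[]), FS)
        assert all(np.isnan(v) for v in res.C_avg.values())

    def test_ankle_out_of_phase_excluded(self):
        rng = np.random.default_rng(45)
        cycles = _cycles(3)
        for c in cycles.cycles:
            c.flex_ankle_in_phase = False
            c.ext_ankle_in_phase = False
        n = cycles.cycles[-1].extension[1] + 10
        hip = rng.normal(0, 20, n)
        rates = {"hip_flex": hip, "knee_flex": hip, "ankle_flex": hip}
        res = interjoint_coordination(rates, cycles, FS)
        assert np.isnan(res.C_avg["HA"]) and np.isnan(res.C_avg["KA"])
        assert res.C_avg["HK"] == pytest.approx(1.0)

    def test_independent_walks_near_zero(self):
        rng = np.random.default_rng(46)
        cycles = _cycles(50, window=100, gap=20)
        n = cycles.cycles[-1].extension[1] + 10
        rates = {k: rng.normal(0, 20, n)
                 for k in ("hip_flex", "knee_flex", "ankle_flex")}
        res = interjoint_coordination(rates, cycles, FS)
        assert abs(res.C_avg["HK"]) < 0.3


class TestOutlierFilter:
    def test_strict_boundary(self):
        rng = np.random.default_rng(47)
        rows = []
        for f in (0.85, 0.90, 0.95):
            r = random_feature_row(rng)
            r.F_act, r.F_rest = f, 1.0 - f
            r.F_B, r.F_UL, r.F_UR, r.F_UP = f, 0.0, 0.0, 0.0
            rows.append(r)
        kept = segment_outlier_filter(rows)
        assert [r.F_act for r in kept] == [0.85, 0.90]

    def test_rest_side_also_filtered(self):
        rng = np.random.default_rng(48)
        r = random_feature_row(rng)
        r.F_act, r.F_rest, r.F_B, r.F_UL, r.F_UR, r.F_UP = 0.05, 0.95, 0.05, 0, 0, 0
        assert segment_outlier_filter([r]) == []

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(49)
        rows = [random_feature_row(rng, i) for i in range(200)]
        kept = segment_outlier_filter(rows)
        expect = [r for r in rows if r.F_act <= 0.9 and r.F_rest <= 0.9]
        assert kept == expect


class TestSessionMedians:
    def _rows(self, values, name="D_avg_kick"):
        rng = np.random.default_rng(50)
        rows = []
        for i, v in enumerate(values):
            r = random_feature_row(rng, i)
            setattr(r, name, v)
            r.D_max_kick = max(v, r.D_max_kick) if not np.isnan(v) else r.D_max_kick
            rows.append(r)
        return rows

    def test_odd_count(self):
        s = session_medians(self._rows([1.0, 5.0, 100.0]), "i", 20.0)
        assert s.features["D_avg_kick"] == 5.0

    def test_even_count_mean_of_middle(self):
        s = session_medians(self._rows([1.0, 3.0]), "i", 20.0)
        assert s.features["D_avg_kick"] == 2.0

    def test_undefined_masked(self):
        rng = np.random.default_rng(51)
        rows = [random_feature_row(rng, i) for i in range(5)]
        for r in rows[:4]:
            r.C_HK = float("nan")
        rows[4].C_HK = 0.25
        s = session_medians(rows, "i", 20.0)
        assert s.features["C_HK"] == 0.25
        for r in rows:
            r.C_HK = float("nan")
        assert np.isnan(session_medians(rows, "i", 20.0).features["C_HK"])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(52)
        rows = [random_feature_row(rng, i) for i in range(31)]
        s = session_medians(rows, "i", 20.0)
        vals = sorted(r.A_avg for r in rows)
        assert s.features["A_avg"] == pytest.approx(vals[15])

    def test_no_rows_rejected(self):
        with pytest.raises(ValueError):
            session_medians([], "i", 20.0)


def test_all_rest_segment_baseline():
    """An all-rest segment yields the rest-state value of every feature."""
    n = 6000
    streams = {}
    for side in ("left", "right"):
        for seg in ("thigh", "shin", "foot"):
            sid = f"{side}_{seg}"
            streams[sid] = SensorStream(sensor_id=sid, sample_rate=FS,
                                        t=np.arange(n) / FS,
                                        gyro=np.zeros((n, 3)),
                                        accel=np.zeros((n, 3)))
    segment = Segment(index=0, start_time=0.0, n_samples=n, sample_rate=FS,
                      streams=streams)
    row = extract_features(segment, default_axes(), "right")
    assert row.F_act == 0.0 and row.F_rest == 1.0
    assert row.D_avg_kick == row.D_max_kick == 0.0
    assert row.D_max_rest == 60.0
    assert np.isnan(row.A_avg) and np.isnan(row.C_HK)
    assert all(v == 0.0 for v in row.Emax_pos.values())
    assert row.K == 0


def test_extracted_activity_fraction_matches_truth(sim_session, extracted):
    cfg, _, truth = sim_session
    rows, _, _ = extracted
    for row in rows:
        start = cfg.calibration_s + row.segment_index * 60.0
        tf = truth.segment_features(start, start + 60.0)
        assert row.F_act == pytest.approx(tf["F_act"], abs=0.05)
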