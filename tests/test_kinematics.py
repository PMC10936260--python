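"""Joint axes, DOF rates, phase labeling and excursions."""

import numpy as np
import pytest

from kicksense.kinematics import (
    ExcursionRecord,
    _sign_runs,
    compute_leg_dofs,
    default_axes,
    dof_phase,
    estimate_joint_axes,
    integrate_angles,
    joint_angular_rates,
    max_excursions,
)

FS = 100.0


def _asym_pulse(n_up=30, n_down=60, rate_up=40.0):
    """Baseline-returning pulse with a faster positive stroke."""
    rate_down = rate_up * n_up / n_down
    return np.concatenate([np.full(n_up, rate_up), np.full(n_down, -rate_down)])


class TestJointAxes:
    def test_known_hip_axis_recovered(self):
        rng = np.random.default_rng(20)
        axis = np.array([0.8, 0.6, 0.0])
        pulse = np.concatenate([_asym_pulse()] * 10)
        n = len(pulse)
        thigh = np.outer(pulse, axis) + rng.normal(0, 0.3, (n, 3))
        zero = np.zeros((n, 3))
        axes = estimate_joint_axes(thigh, thigh + zero, thigh + zero,
                                   np.ones(n))
        est = axes.axes["hip_flex"]
        angle = np.degrees(np.arccos(np.clip(abs(est @ axis), -1, 1)))
        assert angle < 2.0
        assert est @ axis > 0  # faster stroke direction is positive

    def test_all_rest_rejected(self):
        z = np.zeros((100, 3))
        with pytest.raises(ValueError, match="no motion"):
            estimate_joint_axes(z, z, z, np.zeros(100))

    def test_sign_convention_invariant_to_input_flip(self):
        pulse = np.concatenate([_asym_pulse()] * 5)
        n = len(pulse)
        thigh = np.outer(pulse, [1.0, 0, 0])
        a1 = estimate_joint_axes(thigh, thigh, thigh, np.ones(n))
        # the same motion observed through a flipped sensor axis
        a2 = estimate_joint_axes(-thigh, -thigh, -thigh, np.ones(n))
        np.testing.assert_allclose(a1.axes["hip_flex"] @ np.array([1.0, 0, 0]),
                                   -(a2.axes["hip_flex"] @ np.array([1.0, 0, 0])),
                                   atol=1e-9)


class TestJointRates:
    def test_pure_hip_flexion_isolated(self):
        n = 500
        thigh = np.zeros((n, 3))
        thigh[:, 0] = 30.0
        shin = thigh.copy()
        foot = thigh.copy()
        series = joint_angular_rates(thigh, shin, foot, default_axes(), FS)
        np.testing.assert_allclose(series["hip_flex"].rate, 30.0)
        for dof in ("hip_abd", "hip_rot", "knee_flex", "ankle_flex", "ankle_inv"):
            assert np.all(np.abs(series[dof].rate) < 1.0)

    def test_zero_input_zero_rates(self):
        z = np.zeros((100, 3))
        series = joint_angular_rates(z, z, z, default_axes(), FS)
        for s in series.values():
            np.testing.assert_array_equal(s.rate, 0.0)

    def test_projection_linearity(self):
        rng = np.random.default_rng(21)
        t1, s1, f1 = (rng.normal(0, 10, (200, 3)) for _ in range(3))
        t2, s2, f2 = (rng.normal(0, 10, (200, 3)) for _ in range(3))
        ax = default_axes()
        r1 = joint_angular_rates(t1, s1, f1, ax, FS)
        r2 = joint_angular_rates(t2, s2, f2, ax, FS)
        r12 = joint_angular_rates(t1 + t2, s1 + s2, f1 + f2, ax, FS)
        for dof in r1:
            np.testing.assert_allclose(r12[dof].rate,
                                       r1[dof].rate + r2[dof].rate, atol=1e-9)


class TestPhase:
    def test_fast_constant_rate_is_moving(self):
        rate = np.full(200, 10.0)  # 10 deg/s for 2 s
        assert np.all(dof_phase(rate, FS) == 1)

    def test_slow_rotation_is_rest(self):
        # 4 deg/s for 1 s: 4 degrees < 5-degree rule
        rate = np.zeros(400)
        rate[100:200] = 4.0
        assert np.all(dof_phase(rate, FS) == 0)

    def test_boundary_change_is_moving(self):
        rate = np.zeros(400)
        rate[100:200] = 5.0  # exactly 5 degrees per 1 s
        phase = dof_phase(rate, FS)
        assert np.all(phase[100:200] == 1)

    def test_triangle_wave_alternates_at_zero_crossings(self):
        t = np.arange(1200) / FS
        rate = 20.0 * np.sign(np.sin(2 * np.pi * t / 4.0))  # 2 s half-periods
        phase = dof_phase(rate, FS)
        np.testing.assert_array_equal(phase, np.sign(rate).astype(np.int8))

    def test_phase_partitions_every_sample(self):
        rng = np.random.default_rng(22)
        rate = rng.normal(0, 30, 2000)
        phase = dof_phase(rate, FS)
        assert set(np.unique(phase)) <= {-1, 0, 1}
        runs = _sign_runs(phase)
        assert runs[0][0] == 0 and runs[-1][1] == len(phase)
        assert all(a[1] == b[0] for a, b in zip(runs, runs[1:]))


class TestIntegration:
    def test_positive_run_excursion(self):
        rate = np.full(200, 10.0)
        phase = dof_phase(rate, FS)
        _, rec = integrate_angles(rate, phase, FS)
        assert rec.positive == [pytest.approx(20.0)]

    def test_negative_run_excursion(self):
        rate = np.full(100, -15.0)
        phase = dof_phase(rate, FS)
        _, rec = integrate_angles(rate, phase, FS)
        assert rec.negative == [pytest.approx(15.0)]

    def test_matches_riemann_oracle(self):
        rng = np.random.default_rng(23)
        # piecewise-constant rates, strongly signed so no rest relabeling
        segments = rng.choice([40.0, -40.0, 25.0, -25.0], size=20)
        rate = np.repeat(segments, rng.integers(30, 120, size=20))
        phase = dof_phase(rate, FS)
        _, rec = integrate_angles(rate, phase, FS)
        got = sorted(rec.positive + rec.negative)
        expected = []
        for a, b, lab in _sign_runs(np.sign(rate).astype(int)):
            if lab != 0:
                expected.append(abs(sum(rate[a:b]) / FS))
        assert got == pytest.approx(sorted(expected), abs=1e-6)

    def test_angle_resets_at_run_start(self):
        rate = np.concatenate([np.full(100, 20.0), np.full(100, -20.0)])
        phase = dof_phase(rate, FS)
        angle, _ = integrate_angles(rate, phase, FS)
        assert angle[0] == pytest.approx(0.2)  # one sample into the run
        assert angle[100] == pytest.approx(-0.2)  # reset at the new run


class TestMaxExcursions:
    def test_max_and_empty(self):
        rec = ExcursionRecord(dof="hip_flex", positive=[20.0, 5.0, 12.0],
                              negative=[])
        assert max_excursions(rec) == (20.0, 0.0)

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            pos = list(rng.uniform(0, 40, rng.integers(0, 10)))
            neg = list(rng.uniform(0, 40, rng.integers(0, 10)))
            rec = ExcursionRecord(dof="x", positive=pos, negative=neg)
            ep, en = max_excursions(rec)
            assert ep == (max(pos) if pos else 0.0)
            assert en == (max(neg) if neg else 0.0)


def test_excursion_recovery_from_simulator(sim_session):
    """Programmed pulse amplitudes are recovered per run after preprocessing.

    Uses the generator's anatomically aligned axes, so the check isolates
    preprocessing + phase labeling + integration; PCA axis estimation has
    its own accuracy test above.
    """
    from kicksense.preprocessing import preprocess_recording

    cfg, rec, truth = sim_session
    clean, activity = preprocess_recording(rec)
    checked = 0
    for pred in ("left", "right"):
        thigh, shin, foot = clean.leg_streams(pred)
        series = compute_leg_dofs(thigh.gyro, shin.gyro, foot.gyro,
                                  default_axes(), FS)
        for dof in ("hip_flex", "knee_flex"):
            s = series[dof]
            runs = [(a, b) for a, b, lab in _sign_runs(s.phase) if lab == 1]
            for ev in truth.events:
                if pred not in ev.sides:
                    continue
                amp = ev.amplitudes[pred][dof]
                w0, wf = ev.windows[pred][dof]
                i0 = int((ev.start + w0 * ev.duration) * FS)
                i1 = int((ev.start + (w0 + cfg.flex_frac * wf) * ev.duration) * FS)
                overlapping = [r for r in runs if r[0] < i1 and r[1] > i0]
                assert overlapping, f"no flexion run for event at {ev.start:.2f}s"
                a, b = max(overlapping,
                           key=lambda r: min(r[1], i1) - max(r[0], i0))
                exc = abs(np.sum(s.rate[a:b]) / FS)
                assert exc == pytest.approx(amp, abs=max(0.5, 0.02 * amp))
                checked += 1
    assert checked >= 40
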