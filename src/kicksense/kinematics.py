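"""Per-DOF joint angular rates, angles, phase labels and excursions.

Joint motion is recovered from the relative angular rate between the sensors
flanking each joint: with the infant supine the pelvis is taken as
stationary, so hip rate = thigh gyro, knee rate = shin - thigh, ankle rate =
foot - shin.  Joint axes are estimated by principal component analysis of
the relative-rate sample cloud during activity and the per-DOF rate is the
projection onto each axis.  Six DOFs are tracked per leg: hip
flexion/abduction/rotation, knee flexion, ankle flexion/inversion.

Each DOF rate series is labeled with a per-sample *phase*: +1 while the
joint rotates in the positive direction, -1 in the negative direction, and
0 (rest) for any movement run whose angle change stays below 5 degrees per
1 s of movement.  The joint angle is reset to 0 at the start of each phase
run; the magnitude of the angle reached at the end of the run is that run's
*excursion*.

Quadrature convention: each sample represents one sample interval of
movement, so a run of ``n`` samples lasts ``n / fs`` seconds and its
excursion is ``sum(rate) / fs``.  This left-Riemann convention keeps run
duration and excursion exactly consistent for constant-rate motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kicksense.io_model import DOFS

JOINTS = ("hip", "knee", "ankle")
JOINT_DOFS = {
    "hip": ("hip_flex", "hip_abd", "hip_rot"),
    "knee": ("knee_flex",),
    "ankle": ("ankle_flex", "ankle_inv"),
}
DOF_JOINT = {dof: joint for joint, dofs in JOINT_DOFS.items() for dof in dofs}


@dataclass
class JointAxisSet:
    """Unit joint-axis vectors (sensor frame) for each DOF of one leg."""

    axes: dict  # dof -> (3,) unit vector

    def __post_init__(self) -> None:
        for dof, ax in self.axes.items():
            ax = np.asarray(ax, dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError(f"axis for {dof} is not unit norm")
            self.axes[dof] = ax
        for joint, dofs in JOINT_DOFS.items():
            present = [d for d in dofs if d in self.axes]
            for i, a in enumerate(present):
                for b in present[i + 1:]:
                    if abs(self.axes[a] @ self.axes[b]) > 1e-6:
                        raise ValueError(f"{joint} axes {a}/{b} not orthogonal")


@dataclass
class DOFSeries:
    """Angular rate, integrated angle and phase labels for one DOF."""

    dof: str
    sample_rate: float
    rate: np.ndarray  # deg/s
    angle: np.ndarray = field(default=None)  # deg, reset at each phase-run start
    phase: np.ndarray = field(default=None)  # int8 in {-1, 0, +1}


@dataclass
class ExcursionRecord:
    """Per-direction excursions (deg, magnitudes) of a DOF's phase runs."""

    dof: str
    positive: list = field(default_factory=list)  # E+ per positive-phase run
    negative: list = field(default_factory=list)  # E- per negative-phase run

    def __post_init__(self) -> None:
        for store in (self.positive, self.negative):
            if any(v < 0 for v in store):
                raise ValueError("excursions must be non-negative magnitudes")


def default_axes() -> JointAxisSet:
    """Anatomically aligned fallback axes (x flexion, y abduction/inversion,
    z rotation), used when a recording has no motion to estimate from."""
    e = np.eye(3)
    return JointAxisSet(axes={
        "hip_flex": e[0], "hip_abd": e[1], "hip_rot": e[2],
        "knee_flex": e[0], "ankle_flex": e[0], "ankle_inv": e[1],
    })


def relative_rates(thigh_gyro, shin_gyro, foot_gyro) -> dict:
    """Joint relative angular rates (deg/s) in the sensor frame."""
    thigh = np.asarray(thigh_gyro, dtype=float)
    shin = np.asarray(shin_gyro, dtype=float)
    foot = np.asarray(foot_gyro, dtype=float)
    return {"hip": thigh, "knee": shin - thigh, "ankle": foot - shin}


def estimate_joint_axes(
    thigh_gyro, shin_gyro, foot_gyro, active: np.ndarray
) -> JointAxisSet:
    """PCA joint axes from the relative-rate cloud during activity.

    Per joint, the principal directions of the active relative-rate samples
    are ordered by explained variance and mapped to that joint's DOFs (hip:
    flexion, abduction, rotation; knee: flexion; ankle: flexion, inversion).
    Each axis is signed so that the rotation direction with the larger total
    excursion over the span is positive; when the two directions balance
    (motion that returns to baseline), the direction of the faster stroke
    is positive — for kicking, flexion.
    """
    active = np.asarray(active).astype(bool)
    if not active.any():
        raise ValueError("no motion to estimate axes")
    rel = relative_rates(thigh_gyro, shin_gyro, foot_gyro)
    axes = {}
    for joint, dofs in JOINT_DOFS.items():
        cloud = rel[joint][active]
        # uncentered principal directions: rest-dominated rates are zero-mean
        _, _, vt = np.linalg.svd(cloud, full_matrices=False)
        for k, dof in enumerate(dofs):
            ax = vt[k]
            proj = cloud @ ax
            pos = proj[proj > 0].sum()
            neg = -proj[proj < 0].sum()
            if pos + neg > 0 and abs(pos - neg) > 0.05 * (pos + neg):
                flip = pos < neg
            else:
                # baseline-returning motion has balanced excursion mass;
                # disambiguate by rate skewness (the faster stroke wins)
                flip = (proj ** 3).sum() < 0
            axes[dof] = -ax if flip else ax
    return JointAxisSet(axes=axes)


def joint_angular_rates(
    thigh_gyro, shin_gyro, foot_gyro, axes: JointAxisSet, sample_rate: float
) -> dict:
    """Project joint relative rates onto each DOF axis.

    Returns a dict ``dof -> DOFSeries`` (rates only; phase/angle unset).
    """
    rel = relative_rates(thigh_gyro, shin_gyro, foot_gyro)
    out = {}
    for dof, ax in axes.axes.items():
        out[dof] = DOFSeries(
            dof=dof, sample_rate=sample_rate, rate=rel[DOF_JOINT[dof]] @ ax
        )
    return out


def _sign_runs(labels: np.ndarray) -> list:
    """Maximal runs of equal label as (start, stop, label)."""
    n = len(labels)
    if n == 0:
        return []
    change = np.nonzero(np.diff(labels))[0] + 1
    bounds = [0, *change.tolist(), n]
    return [(bounds[i], bounds[i + 1], int(labels[bounds[i]]))
            for i in range(len(bounds) - 1)]


def dof_phase(
    rate: np.ndarray,
    sample_rate: float,
    rest_deg: float = 5.0,
    rest_window_s: float = 1.0,
) -> np.ndarray:
    """Per-sample phase labels {-1, 0, +1} for one DOF.

    Samples are first labeled by the sign of the angular rate (exact zeros
    inside a run carry the preceding nonzero sign, avoiding single-sample
    fragmentation).  Each maximal signed run is then relabeled 0 (rest) if
    its angle change stays below ``rest_deg`` over every ``rest_window_s``
    sliding window; runs shorter than the window use their total change.
    """
    rate = np.asarray(rate, dtype=float)
    labels = np.sign(rate).astype(np.int8)
    # forward-fill exact zeros with the previous nonzero sign
    nz = labels != 0
    idx = np.where(nz, np.arange(len(labels)), -1)
    np.maximum.accumulate(idx, out=idx)
    labels = np.where(idx >= 0, labels[np.maximum(idx, 0)], 0).astype(np.int8)

    win = max(1, int(round(rest_window_s * sample_rate)))
    out = labels.copy()
    for a, b, lab in _sign_runs(labels):
        if lab == 0:
            continue
        csum = np.concatenate([[0.0], np.cumsum(rate[a:b]) / sample_rate])
        n = b - a
        if n >= win:
            changes = np.abs(csum[win:] - csum[:-win])
        else:
            changes = np.abs(csum[-1:])
        if changes.max() < rest_deg:
            out[a:b] = 0
    return out


def integrate_angles(
    rate: np.ndarray, phase: np.ndarray, sample_rate: float, dof: str = ""
) -> tuple:
    """Angle series (reset to 0 at each phase-run start) and excursions.

    Within each nonzero phase run the angle is the running Riemann sum of
    the rate from the run start; rest samples are held at 0.  The run's
    excursion is the magnitude of the final angle, stored under E+ or E-
    according to the run's sign.
    """
    rate = np.asarray(rate, dtype=float)
    phase = np.asarray(phase)
    angle = np.zeros_like(rate)
    record = ExcursionRecord(dof=dof)
    for a, b, lab in _sign_runs(phase):
        if lab == 0:
            continue
        seg = np.cumsum(rate[a:b]) / sample_rate
        angle[a:b] = seg
        exc = abs(seg[-1])
        (record.positive if lab > 0 else record.negative).append(float(exc))
    return angle, record


def max_excursions(record: ExcursionRecord) -> tuple:
    """(max E+, max E-) in degrees; an empty direction yields 0."""
    epos = max(record.positive) if record.positive else 0.0
    eneg = max(record.negative) if record.negative else 0.0
    return epos, eneg


def compute_leg_dofs(
    thigh_gyro, shin_gyro, foot_gyro,
    axes: JointAxisSet, sample_rate: float,
    rest_deg: float = 5.0, rest_window_s: float = 1.0,
) -> dict:
    """Full kinematic chain for one leg: rates -> phase -> angles.

    Returns ``dof -> DOFSeries`` with rate, phase and angle populated.
    """
    series = joint_angular_rates(thigh_gyro, shin_gyro, foot_gyro, axes, sample_rate)
    for dof, s in series.items():
        s.phase = dof_phase(s.rate, sample_rate, rest_deg, rest_window_s)
        s.angle, _ = integrate_angles(s.rate, s.phase, sample_rate, dof)
    return series


def leg_excursions(series: dict, sample_rate: float) -> dict:
    """Per-DOF ExcursionRecord for a dict of phase-labeled DOFSeries."""
    out = {}
    for dof in DOFS:
        if dof not in series:
            continue
        s = series[dof]
        _, rec = integrate_angles(s.rate, s.phase, sample_rate, dof)
        out[dof] = rec
    return out
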