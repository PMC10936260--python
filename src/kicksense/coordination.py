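"""Activity/coordination vectors, predominant leg, and kick-cycle detection.

The per-leg binary activity series are combined into an overall gross
activity vector (logical OR) and a four-state coordination vector: 0 rest,
1 unilateral left, 2 unilateral right, 3 bilateral.  The predominant leg is
the leg with the higher total frequency of movement over a session.

A *kick cycle* is a period of full flexion followed by a period of full
extension: the hip and knee must flex simultaneously for at least 50 ms
with either joint's excursion exceeding 11.5 degrees, and must subsequently
extend simultaneously.  The ankle need not move in phase with the hip and
knee; per-cycle flags record whether it did.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kicksense.kinematics import DOFSeries, _sign_runs
from kicksense.preprocessing import binary_runs


@dataclass
class ActivityVector:
    """Per-leg and combined gross activity over one segment."""

    S_L: np.ndarray
    S_R: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.S_L) == len(self.S_R) == len(self.S)):
            raise ValueError("activity vector length mismatch")


@dataclass
class CoordinationVector:
    """Per-sample coordination codes over one segment (0/1/2/3)."""

    V: np.ndarray

    def __post_init__(self) -> None:
        if not np.all((self.V >= 0) & (self.V <= 3)):
            raise ValueError("coordination codes must be in {0,1,2,3}")


@dataclass
class KickCycle:
    """One full-flexion/full-extension pair (half-open sample ranges)."""

    flexion: tuple  # (start, stop)
    extension: tuple  # (start, stop)
    flex_ankle_in_phase: bool
    ext_ankle_in_phase: bool
    hip_excursion: float  # deg, within the flexion run
    knee_excursion: float  # deg, within the flexion run


@dataclass
class KickCycleSet:
    """Ordered, non-overlapping kick cycles of one segment."""

    cycles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for c in self.cycles:
            if c.extension[0] < c.flexion[1]:
                raise ValueError("extension starts before flexion ends")
            if c.flexion[0] < prev_end:
                raise ValueError("kick cycles overlap")
            prev_end = c.extension[1]

    @property
    def K(self) -> int:
        return len(self.cycles)


def combine_activity(S_L, S_R) -> ActivityVector:
    """Element-wise OR of the two leg activity vectors."""
    S_L = np.asarray(S_L, dtype=np.uint8)
    S_R = np.asarray(S_R, dtype=np.uint8)
    if len(S_L) != len(S_R):
        raise ValueError(f"length mismatch: {len(S_L)} vs {len(S_R)}")
    return ActivityVector(S_L=S_L, S_R=S_R, S=(S_L | S_R).astype(np.uint8))


def coordination_vector(S_L, S_R) -> CoordinationVector:
    """0 rest, 1 unilateral left, 2 unilateral right, 3 bilateral."""
    S_L = np.asarray(S_L, dtype=np.uint8)
    S_R = np.asarray(S_R, dtype=np.uint8)
    if len(S_L) != len(S_R):
        raise ValueError(f"length mismatch: {len(S_L)} vs {len(S_R)}")
    return CoordinationVector(V=(S_L + 2 * S_R).astype(np.uint8))


def predominant_leg(S_L, S_R) -> str:
    """Side with the larger total active-sample count; ties go right."""
    left = int(np.asarray(S_L).sum())
    right = int(np.asarray(S_R).sum())
    return "left" if left > right else "right"


def detect_kick_cycles(
    hip: DOFSeries,
    knee: DOFSeries,
    ankle: DOFSeries,
    min_flex_s: float = 0.05,
    min_excursion_deg: float = 11.5,
) -> KickCycleSet:
    """Detect kick cycles from hip/knee/ankle flexion phase series.

    Full flexion: a maximal run with hip and knee phase both +1, lasting at
    least ``min_flex_s``, whose larger within-run excursion (hip or knee)
    strictly exceeds ``min_excursion_deg``.  The next maximal run with both
    phases -1 is the matching full extension; intervening rest is allowed,
    but a new flexion onset of either joint cancels the pending flexion.
    """
    fs = hip.sample_rate
    hp, kp, ap = hip.phase, knee.phase, ankle.phase
    min_flex = int(round(min_flex_s * fs))

    conj_flex = (hp == 1) & (kp == 1)
    conj_ext = (hp == -1) & (kp == -1)
    any_flex = (hp == 1) | (kp == 1)

    def run_excursion(rate, a, b):
        return abs(float(np.sum(rate[a:b])) / fs)

    events = []  # (start, priority, kind, payload)
    for a, b in binary_runs(any_flex):
        events.append((a, 0, "onset", None))
    for a, b in binary_runs(conj_flex):
        if b - a < min_flex:
            continue
        he = run_excursion(hip.rate, a, b)
        ke = run_excursion(knee.rate, a, b)
        if max(he, ke) > min_excursion_deg:
            events.append((a, 1, "flex", (a, b, he, ke)))
    for a, b in binary_runs(conj_ext):
        events.append((a, 2, "ext", (a, b)))
    events.sort(key=lambda e: (e[0], e[1]))

    def in_phase(phase_series, a, b, sign):
        return float(np.mean(phase_series[a:b] == sign)) > 0.5

    cycles = []
    pending = None
    for start, _, kind, payload in events:
        if kind == "onset":
            if pending is not None and start >= pending[1]:
                pending = None  # a new flexion begins: cancel the stale one
        elif kind == "flex":
            pending = payload
        else:  # extension run
            if pending is not None:
                fa, fb, he, ke = pending
                ea, eb = payload
                if ea >= fb:
                    cycles.append(KickCycle(
                        flexion=(fa, fb), extension=(ea, eb),
                        flex_ankle_in_phase=in_phase(ap, fa, fb, 1),
                        ext_ankle_in_phase=in_phase(ap, ea, eb, -1),
                        hip_excursion=he, knee_excursion=ke,
                    ))
                    pending = None
    return KickCycleSet(cycles=cycles)
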