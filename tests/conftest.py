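import numpy as np
import pytest

from kicksense.io_model import DOFS, FeatureRow
from kicksense.synthetic_kicking import SimConfig, simulate_session


@pytest.fixture(scope="session")
def sim_session():
    """One moderate synthetic session shared by end-to-end tests."""
    cfg = SimConfig(seed=3, session_s=180.0)
    rec, truth = simulate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def extracted(sim_session):
    from kicksense.features import extract_session

    cfg, rec, truth = sim_session
    rows, meta = extract_session(rec)
    return rows, meta, truth


def random_feature_row(rng: np.random.Generator, index: int = 0) -> FeatureRow:
    """A FeatureRow with internally consistent invariants."""
    n = 6000
    n_b, n_ul, n_ur = rng.multinomial(rng.integers(0, n + 1), [1 / 3] * 3)
    f_b, f_ul, f_ur = n_b / n, n_ul / n, n_ur / n
    f_act = f_b + f_ul + f_ur
    d_avg_kick = float(rng.uniform(0, 5))
    d_avg_rest = float(rng.uniform(0, 5))
    a_avg = float(rng.uniform(0, 2))
    undefined = rng.random() < 0.3
    return FeatureRow(
        segment_index=index,
        F_act=f_act, F_rest=1.0 - f_act, F_B=f_b, F_UL=f_ul, F_UR=f_ur,
        F_UP=max(f_ul, f_ur),
        D_avg_kick=d_avg_kick, D_max_kick=d_avg_kick * float(rng.uniform(1, 3)),
        D_avg_rest=d_avg_rest, D_max_rest=d_avg_rest * float(rng.uniform(1, 3)),
        A_avg=a_avg, A_peak=a_avg * float(rng.uniform(1, 2)),
        C_HK=float("nan") if undefined else float(rng.uniform(-1, 1)),
        C_HA=float("nan") if undefined else float(rng.uniform(-1, 1)),
        C_KA=float("nan") if undefined else float(rng.uniform(-1, 1)),
        Emax_pos={d: float(rng.uniform(0, 40)) for d in DOFS},
        Emax_neg={d: float(rng.uniform(0, 40)) for d in DOFS},
        predominant_leg=str(rng.choice(["left", "right"])),
        K=int(rng.integers(0, 10)),
    )
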