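import numpy as np
import pandas as pd
import pytest

from rhythmix.synth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with moderate rhythmicity and some DE transcripts."""
    cfg = SimConfig(n_participants=10, n_transcripts=150, seed=11,
                    frac_de=0.1, de_effect=1.2)
    gem, meta, mel, truth = generate_cohort(cfg)
    return cfg, gem, meta, mel, truth


@pytest.fixture()
def balanced_session():
    """One clean session: 12 participants × 6 aligned 4-h time points."""
    rng = np.random.default_rng(5)
    P, tp = 12, np.array([15.0, 19.0, 23.0, 27.0, 31.0, 35.0])
    offs = rng.normal(8.0, 0.6, P)
    rows = []
    for i in range(P):
        for k, t in enumerate(tp):
            rows.append({"sample_id": f"P{i:02d}_TP{k}", "participant": f"P{i:02d}",
                         "session": "S1", "clock_time": t % 24, "time_index": k,
                         "aligned_time": t - offs[i]})
    return pd.DataFrame(rows)


def ols_cosinor(y, t, tau=24.0, intercept=True):
    """Independent closed-form least-squares cosinor used as an oracle."""
    x1 = np.cos(2 * np.pi * t / tau)
    x2 = np.sin(2 * np.pi * t / tau)
    X = np.column_stack([np.ones_like(t), x1, x2] if intercept else [x1, x2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta
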