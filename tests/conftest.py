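import numpy as np
import pandas as pd
import pytest

from growthmix import (
    BasisSpec,
    ConditionParams,
    LongitudinalDataset,
    MeanModelSpec,
    MembershipModelSpec,
    RandomEffectsSpec,
    SimulationCondition,
)


def make_random_dataset(rng: np.random.Generator, n_subjects: int = 8,
                        n_baselines: int = 2) -> LongitudinalDataset:
    """Small random long-format dataset with per-subject visit schedules."""
    rows = []
    bl = {}
    for i in range(n_subjects):
        sid = f"p{i:03d}"
        n_i = int(rng.integers(1, 6))
        times = np.sort(rng.choice(np.arange(1, 14, 0.25), size=n_i, replace=False))
        for t in times:
            rows.append({"subject": sid, "time": float(t),
                         "y": float(rng.normal(16, 2))})
        bl[sid] = {f"w{j + 1}": float(np.round(rng.normal(), 6)) for j in range(n_baselines)}
    obs = pd.DataFrame(rows)
    baselines = pd.DataFrame.from_dict(bl, orient="index")
    baselines.index.name = "subject"
    return LongitudinalDataset.from_frames(obs, baselines)


@pytest.fixture(scope="session")
def linear_mean_spec():
    return MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w1", "w2"))


@pytest.fixture(scope="session")
def membership_w1w2():
    return MembershipModelSpec(("w1", "w2"))


@pytest.fixture(scope="session")
def intercept_re():
    return RandomEffectsSpec("intercept_only")


@pytest.fixture(scope="session")
def separated_3class_condition():
    """Stochastic linear-growth condition with classes far apart
    (inter-class gaps of 5 outcome units = 10 residual SDs)."""
    params = ConditionParams(
        n_subjects=500,
        class_coefs=((12.0, 0.2), (17.0, 0.5), (22.0, 0.8)),
        class_logits=((0.5, 0.3, 0.8), (-0.2, 0.2, -0.5), (0.0, 0.0, 0.0)),
        re_sd=(0.4,),
        noise_sd=0.5,
        seed=2026,
    )
    return SimulationCondition("stochastic", "linear", "linear", params)
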