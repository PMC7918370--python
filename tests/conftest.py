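import numpy as np
import pandas as pd
import pytest

from tsgc import Panel, SimConfig, NoiseSpec, generate_panel


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """2 subjects x 3 timepoints, 2 groups, complete grid."""
    rows = []
    for subj, grp, vals in [("a", "G1", [2.0, 4.0, 6.0]), ("b", "G2", [1.0, 1.5, 2.0])]:
        for t, v in enumerate(vals, start=1):
            rows.append(
                {"subject": subj, "group": grp, "replicate": 1,
                 "experiment": 1, "time": t, "value": v}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel(tiny_frame) -> Panel:
    return Panel.from_frame(tiny_frame)


@pytest.fixture(scope="session")
def small_iid_panel():
    """9 subjects x 41 timepoints, IID noise, distinct group offsets."""
    cfg = SimConfig(
        n_experiments=1,
        replicas_per_experiment=3,
        n_timepoints=41,
        noise=NoiseSpec(kind="iid", sd=0.03),
        seed=11,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_ar_panel():
    """9 subjects x 41 timepoints with AR(1) phi=0.8 residual noise."""
    cfg = SimConfig(
        n_experiments=1,
        replicas_per_experiment=3,
        n_timepoints=41,
        noise=NoiseSpec(kind="ar1", phi=0.8, sd=0.02),
        seed=12,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
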