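import numpy as np
import pandas as pd
import pytest

from champs_traj.gbtm import GbtmParams, TrajectorySpec
from champs_traj.synthetic_cohort import generate_model_faithful_panel


@pytest.fixture(scope="session")
def separated_3group_params():
    """Well-separated three-group truth used across recovery tests."""
    spec = TrajectorySpec(3, order=3, age_center=11.0, age_scale=5.0)
    beta = np.array([
        [0.5, 0.5, 0.0, 0.0],
        [3.5, 1.0, 0.0, 0.0],
        [6.5, -0.5, 0.5, 0.0],
    ])
    params = GbtmParams(beta=beta, sigma=1.0,
                        theta=np.log(np.array([0.4, 0.3]) / 0.3))
    return spec, params


@pytest.fixture(scope="session")
def small_panel(separated_3group_params):
    """60 children x 20 months from the censored-normal truth."""
    spec, params = separated_3group_params
    panel, truth = generate_model_faithful_panel(
        params, spec, np.linspace(6, 16, 20), n_children=60, seed=2
    )
    return panel, truth


@pytest.fixture()
def reference_tertile_counts():
    """Reference tertile-by-group contingency counts (total motor score)."""
    counts = {1: (67, 50, 28), 2: (108, 99, 77), 3: (106, 103, 105),
              4: (72, 83, 108), 5: (18, 35, 50)}
    rows = []
    for g, (lo, mid, hi) in counts.items():
        rows += [(g, "low")] * lo + [(g, "middle")] * mid + [(g, "high")] * hi
    df = pd.DataFrame(rows, columns=["group", "tertile"])
    design = pd.DataFrame({
        "middle": (df["tertile"] == "middle").astype(float),
        "high": (df["tertile"] == "high").astype(float),
    })
    return df, design
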