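import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from allelenoise import SimulationParams, render_image_stack, simulate_population


@pytest.fixture
def quiet_params():
    """All noise sources off: every cell should land exactly on the diagonal."""
    return SimulationParams(
        silencing_q=0.0,
        sigma_extrinsic=0.0,
        sigma_intrinsic=0.0,
        measurement_sd=0.0,
        gain_red=1.0,
        gain_green=1.0,
        base_expression=5.0,
        seed=11,
    )


@pytest.fixture
def small_dataset():
    """One experiment, hand-written paired intensities."""
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "experiment_id": ["e1"] * 3,
            "group_label": ["g"] * 3,
            "tissue": ["muscle"] * 3,
            "x": [2.0, 1.0, 3.0],
            "y": [1.0, 2.0, 3.0],
        }
    )


@pytest.fixture(scope="session")
def rendered_scene():
    """20 simulated cells rendered as nuclei, with ground truth."""
    params = SimulationParams(
        silencing_q=0.02, n_experiments=1, cells_per_experiment=20, seed=7
    )
    cells, _ = simulate_population(params)
    stack, rois = render_image_stack(cells, seed=3)
    return cells, stack, rois


def match_by_centroid(measured: pd.DataFrame, rois: pd.DataFrame):
    """Pair measured nuclei with ground-truth ROIs by nearest centroid."""
    from scipy.spatial import cKDTree

    tree = cKDTree(measured[["z", "y", "x"]])
    dist, idx = tree.query(rois[["z", "y", "x"]])
    got = measured.iloc[idx][["red_mean", "green_mean"]].to_numpy()
    true = rois[["true_red", "true_green"]].to_numpy()
    return dist, got, true
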