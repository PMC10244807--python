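import numpy as np
import pandas as pd
import pytest

from nanofa.synthetic import SceneConfig, generate_fa_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def square_scene():
    """Small islands-in-clusters scene with known ground truth."""
    w, h = 4000.0, 3000.0
    cfg = SceneConfig(
        fa_polygon=[(0, 0), (w, 0), (w, h), (0, h)],
        island_diameter_law=32.0, island_density=0.02,
        background_density=0.002, cluster_diameter=300.0,
        islands_per_cluster=8, n_clusters=6, seed=3)
    return cfg, generate_fa_scene(cfg)


@pytest.fixture()
def simple_locs():
    """Tiny hand-written localization table."""
    return pd.DataFrame({
        "frame": [0, 1, 1, 5],
        "x_nm": [100.0, 105.0, 300.0, 102.0],
        "y_nm": [100.0, 103.0, 300.0, 99.0],
        "photons": [50.0, 60.0, 40.0, 55.0],
        "uncertainty_nm": [29.0] * 4,
    })
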