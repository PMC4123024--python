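import numpy as np
import pandas as pd
import pytest

import multilur as ml


def random_road_scene(rng, n_segments=50, extent=2000.0):
    """A random road scene around the origin for geometry tests."""
    mid = rng.uniform(-extent, extent, size=(n_segments, 2))
    ang = rng.uniform(0, 2 * np.pi, size=n_segments)
    half = rng.uniform(20.0, 400.0, size=n_segments)
    return pd.DataFrame({
        "segment_id": [f"R{i:03d}" for i in range(n_segments)],
        "x1": mid[:, 0] - half * np.cos(ang),
        "y1": mid[:, 1] - half * np.sin(ang),
        "x2": mid[:, 0] + half * np.cos(ang),
        "y2": mid[:, 1] + half * np.sin(ang),
        "intensity": np.exp(rng.normal(7.0, 1.0, size=n_segments)),
        "is_major": rng.uniform(size=n_segments) < 0.3,
    })


@pytest.fixture(scope="session")
def small_campaign():
    """A small NO2-like campaign shared by read-only tests."""
    cfg = ml.no2_like_config(n_areas=6, sites_per_area=14, seed=11)
    return ml.simulate_campaign(cfg)


@pytest.fixture(scope="session")
def small_model(small_campaign):
    table, y = small_campaign.dataset.design()
    return ml.supervised_stepwise(table, y)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
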