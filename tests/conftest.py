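import numpy as np
import pytest

from kanglnet.pointcloud_io import LabeledCloud, PointCloud
from kanglnet.synthetic_plants import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def small_plant():
    """A 10-silique plant with no injected noise (counting ground truth)."""
    return generate_plant(PlantSpec(n_siliques=10, outlier_fraction=0.0,
                                    small_pod_fraction=0.0,
                                    silique_density=(1300.0, 1700.0),
                                    overlap_level=0.2,
                                    total_points=4000, seed=42))


@pytest.fixture(scope="session")
def default_plant():
    """One default-noise plant in the standard working regime."""
    return generate_plant(PlantSpec(n_siliques=120, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def labeled_cloud(rng):
    """A small random labeled cloud (no geometric structure)."""
    n = 200
    coords = rng.normal(size=(n, 3))
    colors = rng.uniform(size=(n, 3))
    semantic = rng.integers(0, 2, n)
    instance = np.where(semantic == 1, rng.integers(1, 4, n), 0)
    return LabeledCloud(PointCloud(coords, colors), semantic, instance)
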