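import numpy as np
import pandas as pd
import pytest

from rmtbi.core import LabelAtlas, VolumeSeries
from rmtbi.simulate import SimulationConfig, make_phantom_atlas


@pytest.fixture
def small_config():
    """Reduced study for fast unit tests (fewer regions, small grid)."""
    return SimulationConfig(seed=11, grid_shape=(12, 12, 12), n_regions=8)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def phantom_atlas(default_config):
    return make_phantom_atlas(default_config)


@pytest.fixture
def tiny_atlas():
    """Hand-built 3x3x1 atlas with two regions and a blood pool."""
    labels = np.zeros((3, 3, 1), dtype=int)
    labels[0, :, 0] = 1
    labels[1, :, 0] = 2
    labels[2, :, 0] = 3
    regions = pd.DataFrame(
        {
            "label_id": [1, 2, 3],
            "area_name": ["area_a", "area_b", "blood_pool"],
            "hemisphere": ["left", "right", "midline"],
            "region_group": ["thalamus", "cerebellum", "blood"],
        }
    )
    return LabelAtlas(labels=labels, regions=regions)


def volume_like(atlas, values):
    """3D VolumeSeries over the atlas grid filled with `values`."""
    data = np.asarray(values, dtype=float)
    assert data.shape == atlas.labels.shape
    return VolumeSeries(data=data)
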