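import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asoanfis.features import MultispectralScene, SarScene
from asoanfis.raster import Raster
from asoanfis.synthetic import SceneSpec, make_scene


@pytest.fixture(scope="session")
def scene():
    """Small synthetic scene shared by feature-engineering tests."""
    return make_scene(SceneSpec(shape=(48, 48)), seed=11)


@pytest.fixture(scope="session")
def feature_stack(scene):
    from asoanfis.features import build_feature_stack

    ms, sar, _ = scene
    return build_feature_stack(ms, sar)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_raster(data, cell=6.0, origin=(0.0, 0.0)):
    """Raster helper: top-left origin, north-up cells of side ``cell``."""
    data = np.asarray(data, float)
    x0, ytop = origin
    return Raster(data, (x0, ytop + cell * data.shape[0], cell, -cell))


@pytest.fixture
def linear_table(rng):
    """Plot-feature-like table with a linear target over 6 predictors."""
    X = rng.random((120, 6))
    y = 4 * X[:, 0] - 3 * X[:, 1] + 0.05 * rng.standard_normal(120)
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])
    df["agb"] = y
    return df
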