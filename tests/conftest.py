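import numpy as np
import pytest

from vertrom.articulation import neutral_pose
from vertrom.synthetic import (
    ColumnSpec,
    GradientSpec,
    VertebraParams,
    make_column,
    make_sphere_pair,
)


@pytest.fixture(scope="session")
def small_params():
    """Low-resolution vertebra parameters for fast geometry tests."""
    return VertebraParams(mesh_resolution=12)


@pytest.fixture(scope="session")
def small_column(small_params):
    """Three-vertebra column with a mild caudally increasing gradient."""
    spec = ColumnSpec(
        n_vertebrae=3,
        base=small_params,
        gradient=GradientSpec(spine_height=0.5, spine_posterior_angle=1.0),
    )
    return make_column(spec)


@pytest.fixture(scope="session")
def sphere_pair():
    """Unit-sphere oracle fixture with a 0.2 mm gap."""
    return make_sphere_pair(1.0, 0.2)


@pytest.fixture(scope="session")
def sphere_pose(sphere_pair):
    pair, gap = sphere_pair
    return neutral_pose(pair, gaps=[gap])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
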