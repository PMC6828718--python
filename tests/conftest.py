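import numpy as np
import pytest

from actinet import fhn, template


@pytest.fixture(scope="session")
def channel_mask():
    """Short straight channel (width 5) with labelled ends."""
    rec = template.NetworkRecipe(
        kind="straight_channel", shape=(24, 160), channel_length=160, bundle_width=5
    )
    return template.generate_network(rec)


@pytest.fixture(scope="session")
def y_mask():
    rec = template.NetworkRecipe(
        kind="y_junction", shape=(96, 96), bundle_width=5
    )
    return template.generate_network(rec)


@pytest.fixture(scope="session")
def aster_mask():
    rec = template.NetworkRecipe(kind="aster_lattice", shape=(128, 128), seed=7)
    return template.generate_network(rec)


@pytest.fixture
def full_small_mask():
    return template.ConductiveMask(np.ones((9, 9), dtype=bool))


@pytest.fixture
def single_node_mask():
    return template.ConductiveMask(np.ones((1, 1), dtype=bool))


@pytest.fixture
def default_params():
    return fhn.SimulationParams()
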