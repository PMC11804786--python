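import numpy as np
import pytest

from coralflow.geometry import CoralParams, VoxelGeometry, generate_coral


@pytest.fixture(scope="session")
def small_coral_params() -> CoralParams:
    """A reduced coral branch that still has all structural features."""
    return CoralParams(
        shape=(48, 48, 72), cylinder_radius=11.0, cylinder_height=56,
        channel_radius=3.0, n_corallites=8, corallite_radius=2.0,
        bump_amplitude=2.0, apical_radius=4.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_coral(small_coral_params) -> VoxelGeometry:
    return generate_coral(small_coral_params)


@pytest.fixture()
def sealed_cavity_cube() -> np.ndarray:
    """12^3 solid cube with a sealed 4^3 cavity, 2-label scheme (1=solid, 2=pore)."""
    labels = np.full((16, 16, 16), 2, dtype=np.uint8)
    labels[2:14, 2:14, 2:14] = 1
    labels[6:10, 6:10, 6:10] = 2
    return labels
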