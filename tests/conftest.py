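import numpy as np
import pytest

import perfconc as pc


@pytest.fixture(scope="session")
def small_grid():
    return pc.VoxelGrid((16, 16, 12), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def mid_grid():
    return pc.VoxelGrid((32, 32, 24), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def phantom(mid_grid):
    """Lesion-free two-tissue phantom, GM 60 / WM 20 ml/100 g/min."""
    return pc.build_phantom(mid_grid, None, gm_cbf=60.0, wm_cbf=20.0, seed=1)


@pytest.fixture(scope="session")
def aif():
    return pc.gamma_variate_aif(30.0, 30.0, 3.0, np.arange(0.0, 311.0, 0.5))


@pytest.fixture(scope="session")
def schedule():
    return pc.default_frame_schedule()


@pytest.fixture(scope="session")
def scheme():
    return pc.free_lunch_scheme()


@pytest.fixture(scope="session")
def te_params():
    return pc.ASLParams(label_duration=2000.0, post_label_delay=200.0)


@pytest.fixture(scope="session")
def sd_params():
    return pc.ASLParams(label_duration=1800.0, post_label_delay=2000.0)
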