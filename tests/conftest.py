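import numpy as np
import pytest

from prfaniso.hirf import HIRFParams
from prfaniso.stimulus import ScanConfig, rasterize_movie, ring_layout, \
    wedge_layout


@pytest.fixture(scope="session")
def hirf():
    return HIRFParams()


@pytest.fixture(scope="session")
def ring_movie():
    cfg = ScanConfig(aperture_kind="ring_expand", grid_step_deg=0.25)
    return rasterize_movie(cfg, ring_layout())


@pytest.fixture(scope="session")
def wedge_movie():
    cfg = ScanConfig(aperture_kind="wedge_cw", grid_step_deg=0.25)
    return rasterize_movie(cfg, wedge_layout())


@pytest.fixture(scope="session")
def movies(ring_movie, wedge_movie):
    return [ring_movie, wedge_movie]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240213)
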