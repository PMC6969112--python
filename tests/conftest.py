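import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tgdrive import (
    CubeParams,
    LifeHistoryParams,
    architecture,
    build_cube,
    calibrate_life_history,
)


@pytest.fixture(scope="session")
def full_gd():
    return architecture("full_GD")


@pytest.fixture(scope="session")
def full_gdx():
    return architecture("full_GDX")


@pytest.fixture(scope="session")
def tgdc():
    return architecture("tGDc")


@pytest.fixture(scope="session")
def mendelian_full_gd():
    return build_cube("full_GD", CubeParams(q=0.0, c=0.0, d=0.0))


@pytest.fixture(scope="session")
def default_life_history():
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def default_derived(default_life_history):
    return calibrate_life_history(default_life_history)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
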