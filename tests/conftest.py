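import numpy as np
import pytest

from fewview_pocs import (
    build_system_model,
    make_geometry,
    make_reference_phantom,
)


@pytest.fixture(scope="session")
def geom16():
    return make_geometry(4, 20, 16)


@pytest.fixture(scope="session")
def model16(geom16):
    return build_system_model(geom16)


@pytest.fixture(scope="session")
def geom64():
    return make_geometry(8, 64, 64)


@pytest.fixture(scope="session")
def phantom64(geom64):
    return make_reference_phantom(field_of_view=geom64.field_of_view)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
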