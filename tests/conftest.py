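import pytest

from radequiv.materials import silicone, solid_water, water
from radequiv.spectra import co60


@pytest.fixture
def water_mat():
    return water()


@pytest.fixture
def solid_water_mat():
    return solid_water()


@pytest.fixture
def silicone_mat():
    return silicone()


@pytest.fixture
def co60_spec():
    return co60()
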