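import pytest

from sodscan.contacts import ScanParams
from sodscan.fixtures import make_mini_hairpin
from sodscan.rotamers import load_default_library


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def params():
    return ScanParams()


@pytest.fixture(scope="session")
def hairpin():
    return make_mini_hairpin()


@pytest.fixture(scope="session")
def hairpin_protomer(hairpin):
    return hairpin.protomers[0]
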