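import pytest

from algesia_combo.io_model import paperlike_role_map
from algesia_combo.synthetic_data import default_paperlike_config, simulate_dataset


@pytest.fixture(scope="session")
def paperlike_config():
    return default_paperlike_config(seed=0)


@pytest.fixture(scope="session")
def paperlike_dataset(paperlike_config):
    return simulate_dataset(paperlike_config)


@pytest.fixture(scope="session")
def role_map():
    return paperlike_role_map()
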