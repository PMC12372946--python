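import pytest

from ocupk import human_parameters, load_porcine_measurements, porcine_parameters


@pytest.fixture(scope="session")
def human():
    return human_parameters()


@pytest.fixture(scope="session")
def porcine():
    return porcine_parameters()


@pytest.fixture(scope="session")
def porcine_data():
    return load_porcine_measurements()
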