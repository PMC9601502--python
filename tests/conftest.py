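import pytest

from ddquant import datasets


@pytest.fixture(scope="session")
def pork_calibration():
    return datasets.load_calibration_mixtures("pork")


@pytest.fixture(scope="session")
def chicken_calibration():
    return datasets.load_calibration_mixtures("chicken")


@pytest.fixture(scope="session")
def pork_dilution():
    return datasets.load_dilution_series("pork")


@pytest.fixture(scope="session")
def chicken_dilution():
    return datasets.load_dilution_series("chicken")
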