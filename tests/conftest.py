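import pytest

import hrcimpact as h


@pytest.fixture(scope="session")
def cfg_default():
    return h.default_config()


@pytest.fixture(scope="session")
def cfg_calibrated():
    return h.study_calibrated_config()


@pytest.fixture(scope="session")
def baseline_state(cfg_calibrated):
    return h.baseline_from_config(cfg_calibrated)
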