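import numpy as np
import pytest

from isasim.cell import build_cell, build_protocol_cell


@pytest.fixture(scope="session")
def rs_cell():
    return build_cell("RS")


@pytest.fixture(scope="session")
def tor_cell():
    return build_cell("TOR")


@pytest.fixture(scope="session")
def rs_protocol_cell():
    return build_protocol_cell("rs")


@pytest.fixture(scope="session")
def tor_protocol_cell():
    return build_protocol_cell("tor")


@pytest.fixture(scope="session")
def calibrated_steps(rs_cell, tor_cell):
    """Standardized step amplitudes (nA) for the template cells."""
    from isasim.protocols import calibrate_step_amplitude

    return {
        "RS": calibrate_step_amplitude(rs_cell),
        "TOR": calibrate_step_amplitude(tor_cell),
    }
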