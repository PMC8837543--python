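import numpy as np
import pytest

from thrombolyze import default_parameters
from thrombolyze.fixtures import make_minimal_clot
from thrombolyze.transport import run_simulation


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def toy_run():
    """One end-to-end run of the minimal clot fixture (sub-second)."""
    scen, p = make_minimal_clot()
    result = run_simulation(scen, p)
    return scen, p, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
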