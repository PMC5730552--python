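import numpy as np
import pytest

from fgstdp import SynapseParams, fit_stdp, stdp_curve

DT_GRID_MS = np.concatenate([-np.arange(1, 401, 3)[::-1], np.arange(1, 401, 3)])


@pytest.fixture(scope="session")
def params() -> SynapseParams:
    return SynapseParams()


@pytest.fixture(scope="session")
def default_curve(params):
    return stdp_curve(params, DT_GRID_MS.tolist(), v_w0=0.151)


@pytest.fixture(scope="session")
def default_fit(default_curve):
    return fit_stdp(default_curve)
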