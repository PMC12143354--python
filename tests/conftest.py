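import numpy as np
import pytest

from vicombo.design import DEFAULT_DRUGS, build_oacd, monotherapy_runs


@pytest.fixture(scope="session")
def drugs():
    return DEFAULT_DRUGS


@pytest.fixture(scope="session")
def oacd():
    return build_oacd(8)


@pytest.fixture(scope="session")
def screen_design(oacd):
    """OACD plus L1/L2 monotherapies: the 75-run fitting design."""
    return oacd.concat(monotherapy_runs(8))


@pytest.fixture(scope="session")
def coded(screen_design):
    """Coded level matrix {0, 0.5, 1} of the fitting design."""
    x = np.empty(screen_design.runs.shape, dtype=float)
    for code, val in {0: 0.0, 1: 0.5, 2: 1.0}.items():
        x[screen_design.runs == code] = val
    return x
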