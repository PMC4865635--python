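import numpy as np
import pytest

from leachsim.parameters import SoilHorizon, default_ncp_parameters


@pytest.fixture(scope="session")
def ncp_a():
    return default_ncp_parameters("A")


@pytest.fixture(scope="session")
def ncp_b():
    return default_ncp_parameters("B")


@pytest.fixture(scope="session")
def topsoil_a(ncp_a):
    return ncp_a.soil[0]


@pytest.fixture(scope="session")
def uniform_profile():
    """A single homogeneous loam horizon covering the whole column."""
    return (
        SoilHorizon(depth_top=0.0, depth_bottom=210.0, Ksat=1.5, theta_sat=0.40,
                    theta_res=0.06, alpha=0.008, n=1.4, l=0.5, humus=1.0,
                    SOM_fractions=(0.5, 0.4, 0.1), C_per_N=10.0, clay=0.15),
    )
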