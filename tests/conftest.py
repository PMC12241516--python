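import numpy as np
import pytest

from vpdtraits import harness, synthdata
from vpdtraits.aci import KineticConstants


@pytest.fixture(scope="session")
def kin():
    return KineticConstants()


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study run through the whole pipeline (shared)."""
    bundle, truth = synthdata.generate_study(seed=7)
    result = harness.run_study(bundle, varpart_traits=("vcmax25", "chi", "kp"))
    return bundle, truth, result


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-noise study: every measurement equals its generating value."""
    config = synthdata.GradientConfig(noise_scale=0.0)
    bundle, truth = synthdata.generate_study(config, seed=3)
    result = harness.run_study(bundle)
    return bundle, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
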