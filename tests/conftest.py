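import numpy as np
import pytest

from glycoforce import BrushHertzModel, CurveSim, simulate_curve


@pytest.fixture(scope="session")
def noiseless_curve():
    """Default-condition noiseless curve (E* = 2 kPa, L* = 300 nm)."""
    return simulate_curve(CurveSim(noise_sd_pn=0.0), seed=1)


@pytest.fixture(scope="session")
def noiseless_decomposition(noiseless_curve):
    curve, truth = noiseless_curve
    return BrushHertzModel(curve).fit(), truth


@pytest.fixture(scope="session")
def hertz_only_curve():
    """Noiseless pure-Hertz curve (no brush), contact planted at z0 = 500 nm."""
    return simulate_curve(CurveSim(brush=False, noise_sd_pn=0.0, z0_nm=500.0),
                          seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
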