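import numpy as np
import pytest

from crowdtherm import GroundTruth, make_bundle
from crowdtherm.params import CosoluteParams, ProteinCrowdingParams


@pytest.fixture(scope="session")
def noiseless_truth() -> GroundTruth:
    return GroundTruth(sigma_density=0.0, sigma_activity=0.0, sigma_dg=0.0,
                       sigma_mre=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_truth):
    return make_bundle(noiseless_truth, with_spectra=True)


@pytest.fixture(scope="session")
def trehalose_like() -> CosoluteParams:
    """ν ≈ 11.6 disaccharide with χ(298) ≈ 0.32 (χ_H < 0, χ_TS < 0)."""
    return CosoluteParams(name="tre_like", m_c=342.30, vbar_c=209.5,
                          chi_a=2.0, chi_b=-500.0)


@pytest.fixture(scope="session")
def miniprotein() -> ProteinCrowdingParams:
    return ProteinCrowdingParams(name="mini", dsasa=800.0, epsilon=0.3,
                                 eps_h=1.3, eps_s=-1.0, split_set=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
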