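import numpy as np
import pytest

from bnpgcm.gcm import FixedEffects, GrowthDesign, RandomEffectCov, linear_design


@pytest.fixture(scope="session")
def population():
    """Generating values used throughout: beta=(6.2,0.3), Psi=diag(1,0.1), sigma2_e=0.5, T=4."""
    return {
        "fx": FixedEffects(6.2, 0.3),
        "cov": RandomEffectCov(1.0, 0.1, 0.0),
        "sigma2_e": 0.5,
        "design": linear_design(4),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
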