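import numpy as np
import pytest

from hpratio.core import CommunityParams
from hpratio.synth import SynthDesign, generate_raw_campaign, generate_treatments


@pytest.fixture
def lv_params() -> CommunityParams:
    """Cycling LV community with equilibrium ratio k(g-x)/m = 1.8."""
    return CommunityParams(g=0.8, x=0.2, k=0.3, m=0.1, f=0.05)


@pytest.fixture
def zero_noise_records():
    """Treatment records generated exactly from the default truth mapping."""
    design = SynthDesign(noise_sd=0.0)
    records, truth = generate_treatments(design, seed=11)
    return records, truth


@pytest.fixture
def noisy_records():
    records, truth = generate_treatments(SynthDesign(), seed=7)
    return records, truth


@pytest.fixture(scope="session")
def quiet_campaign():
    """Raw campaign with every noise source off, plus its embedded truth."""
    design = SynthDesign(
        noise_sd=0.0,
        pi_noise_sd=0.0,
        profile_noise_sd=0.0,
        cpue_date_cv=0.0,
        biomass_date_cv=0.0,
    )
    return generate_raw_campaign(design, seed=5)


def random_valid_params(rng: np.random.Generator) -> CommunityParams:
    """Coexisting community with moderate cycle period, for property tests."""
    g = rng.uniform(0.5, 1.5)
    return CommunityParams(
        g=g,
        x=rng.uniform(0.0, 0.5) * g,
        k=rng.uniform(0.2, 0.8),
        m=rng.uniform(0.05, 0.3),
        f=rng.uniform(0.02, 0.1),
    )
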