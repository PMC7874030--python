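import numpy as np
import pytest

from synergylab import SyntheticSpec, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trial():
    """Three-repetition synthetic recording with generative truth."""
    spec = SyntheticSpec(seed=42, n_cycles=3)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def recovery_case():
    """The parameter-recovery study conditions: 4 synergies at centers
    25/60/85/120 points, sigma 6, 25 cycles, noise sd 0.05, fixed seed."""
    from synergylab import generate_envelopes

    spec = SyntheticSpec(seed=11)
    v, truth = generate_envelopes(spec)
    return spec, v, truth
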