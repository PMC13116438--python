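import numpy as np
import pytest

import wbequant as w


@pytest.fixture(scope="session")
def panel():
    return w.default_panel()


@pytest.fixture(scope="session")
def small_config():
    """A small but complete batch: 4 biomarkers, 3 sites, 4 weeks."""
    return w.SimConfig(
        seed=7,
        compounds=("amphetamine", "benzoylecgonine", "cocaine", "methamphetamine"),
        n_sites=3,
        n_weeks=4,
    )


@pytest.fixture(scope="session")
def small_batch(small_config, panel):
    return w.simulate_batch(small_config, panel)


def lognoise(rng, cv, size=None):
    """Mean-1 multiplicative lognormal noise (test-side copy of the generator's)."""
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)
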