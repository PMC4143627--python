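import numpy as np
import pytest

from admixscan import simpop


@pytest.fixture(scope="session")
def small_panel():
    """300-SNP, 3-population frequency panel on a 2.217-morgan map."""
    return simpop.draw_ancestral_freqs(300, K=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """80-individual null cohort (no trait effects beyond age/sex)."""
    return simpop.simulate_cohort(small_panel, n=80, g=10.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
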