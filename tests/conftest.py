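import numpy as np
import pytest

from oudup.background import (
    BackgroundDistributions,
    simulate_single_copy_set,
    synthesize_fit_pool,
    background_summaries,
)


@pytest.fixture(scope="session")
def small_background() -> BackgroundDistributions:
    """A 500-gene fixture background, large enough for rank/moment features."""
    fits = synthesize_fit_pool(n=200, m=6, rng=np.random.default_rng(7))
    genes = simulate_single_copy_set(fits, n_genes=500, rng_seed=8)
    return background_summaries(genes)
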