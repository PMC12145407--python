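import numpy as np
import pytest

import navfactor as nf


@pytest.fixture(scope="session")
def spec():
    return nf.default_latent_spec()


@pytest.fixture(scope="session")
def small_cohort(spec):
    """94 participants with raw trial data, the study-scale sample."""
    latents = nf.draw_participants(spec, 94, 101)
    raw = nf.generate_raw_trials(latents, spec, 102)
    return latents, raw


@pytest.fixture(scope="session")
def scored_small(small_cohort):
    _, raw = small_cohort
    return nf.score_participants(raw)


@pytest.fixture(scope="session")
def indicator_table_large(spec):
    """Indicator-level table at n=5000 for recovery checks."""
    latents = nf.draw_participants(spec, 5000, 7)
    return nf.build_indicator_table(nf.generate_indicators(latents, spec, 8)), latents


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
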