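import numpy as np
import pytest

from ephmap.substrate import build_substrate, genotype


@pytest.fixture(scope="session")
def wt_small():
    """Small wild-type substrate shared by analysis/model unit tests."""
    return build_substrate(genotype("wild_type"), 300, 300, seed=11)


@pytest.fixture(scope="session")
def wt_medium():
    """Mid-sized wild-type substrate for fixture-based analysis tests."""
    return build_substrate(genotype("wild_type"), 1000, 1000, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
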