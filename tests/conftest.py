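import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oakwood import phylo, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def balanced_tree():
    """Fixed 4-tip tree with unequal depths for exact-oracle comparisons."""
    return phylo.read_newick("((A:1.0,B:1.0):0.5,(C:0.8,D:0.8):0.7);")


@pytest.fixture(scope="session")
def yule50():
    """A fixed 50-tip pure-birth tree for calibration tests."""
    return simulate.yule_tree(50, np.random.default_rng(777))


@pytest.fixture(scope="session")
def bundle():
    """Default-shape synthetic study bundle (21 species, 33 plots)."""
    return simulate.simulate_study(seed=11)
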