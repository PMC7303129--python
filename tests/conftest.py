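import numpy as np
import pytest

from clonalith.simulate import SimConfig, simulate_tumor


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic simulated tumor bundle + ground truth."""
    cfg = SimConfig(n_regions=4, n_clusters=4, n_mutations=400, n_probes=2000,
                    seed=3)
    return simulate_tumor(cfg, seed=3, tumor_id="pytest_tumor")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
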