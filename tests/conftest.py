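import numpy as np
import pytest

from sekit.simulate import SimParams, simulate


SMALL_SIM = SimParams(
    seed=7,
    n_genes=50,
    n_typical_enhancers=60,
    n_super_enhancers=5,
    n_peaks_per_condition=40,
    n_deg_up=15,
    n_deg_down=10,
    n_proximal_peaks=10,
    chrom_length=3_000_000,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A scaled-down synthetic bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    truth = simulate(SMALL_SIM, out)
    return out, truth, SMALL_SIM


@pytest.fixture
def rng():
    return np.random.default_rng(0)
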