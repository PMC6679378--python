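import numpy as np
import pytest

from eqtlkit import simulate_f2_genotypes, simulate_map
from eqtlkit.genoprob import genotype_probabilities
from eqtlkit.simdata import standard_architecture


@pytest.fixture(scope="session")
def gmap5():
    """Five chromosomes of 100 cM with framework markers every 10 cM."""
    return simulate_map([100.0] * 5, 10.0, 2.0)


@pytest.fixture(scope="session")
def cross123(gmap5):
    """A 123-individual reciprocal F2 cross with no simulated eQTLs."""
    arch = standard_architecture(gmap5, n_null=1, seed=42)
    return simulate_f2_genotypes(gmap5, arch)


@pytest.fixture(scope="session")
def genoprobs123(cross123, gmap5):
    """Marker-grid genotype probabilities for the shared cross."""
    return genotype_probabilities(cross123, gmap5, step_cm=10.0, error_rate=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
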