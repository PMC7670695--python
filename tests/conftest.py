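import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture(scope="session")
def tiny_gmap():
    """Small genome: 2 chromosomes, 30 SNPs + 10 QTL each."""
    from spatialbv import GenomeMap
    return GenomeMap.uniform(n_chromosomes=2, snps_per_chromosome=30,
                             qtl_per_chromosome=10)
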