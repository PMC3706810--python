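import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import popseqsim as pq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_genome():
    """Two short chromosomes for fast unit tests."""
    return pq.GenomeSpec((("c1", 2_000_000), ("c2", 1_500_000)))


@pytest.fixture(scope="session")
def tiny_landscape(tiny_genome):
    land, markers = pq.synthesize_landscape(
        tiny_genome, markers_per_chrom=60, mean_crossovers=1.0, seed=101)
    return land, markers


@pytest.fixture(scope="session")
def tiny_model(tiny_landscape):
    land, markers = tiny_landscape
    return pq.MeiosisModel(land, markers)


@pytest.fixture(scope="session")
def ath_setup():
    """Arabidopsis-like landscape at the density used for analysis checks."""
    land, markers = pq.synthesize_landscape(
        pq.arabidopsis_like(), markers_per_chrom=1000, mean_crossovers=1.0,
        seed=11)
    return land, markers, pq.MeiosisModel(land, markers)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
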