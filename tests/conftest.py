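import numpy as np
import pytest

from recombkit import (
    CarrierEffectSpec,
    ChromosomeModel,
    GenomeModel,
    StahlParams,
    hotspot_mask,
    synthetic_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def toy_genome():
    """Three-chromosome synthetic genome with hotspots and tracks."""
    return synthetic_genome(
        n_chromosomes=3,
        physical_lengths_mb=[200.0, 130.0, 70.0],
        genetic_lengths_cm=[320.0, 215.0, 125.0],
        seed=11,
    )


@pytest.fixture(scope="session")
def flat_chromosome():
    """100 Mb chromosome with a uniform 2 cM/Mb map and no structure."""
    return ChromosomeModel(
        name="chrU",
        physical_length=100_000_000,
        map_anchors=np.array([[0.0, 0.0], [100_000_000.0, 200.0]]),
    )


@pytest.fixture(scope="session")
def flat_genome(flat_chromosome):
    return GenomeModel([flat_chromosome])


@pytest.fixture(scope="session")
def null_spec():
    """Carrier spec with no effect at any dosage."""
    return CarrierEffectSpec.null(StahlParams(nu=6.59, p=0.039))
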