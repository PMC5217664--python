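import numpy as np
import pytest

from mutspot import GenomeIndex, GenomicInterval, SimulationConfig, simulate_cohort
from mutspot.synthetic_fixtures import PlantedRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome(rng):
    """Two 300-bp chromosomes with a fixed random sequence."""
    bases = np.array(list("ACGT"))
    seqs = {
        c: "".join(bases[rng.integers(0, 4, 300)]) for c in ("chr1", "chr2")
    }
    return GenomeIndex({c: 300 for c in seqs}, seqs)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small synthetic cohort with one hotspot and one hypermutated focus."""
    config = SimulationConfig(
        seed=7,
        n_chromosomes=1,
        chrom_length=200_000,
        cohorts={"BRCA-UK": 20, "MALY-DE": 20},
        background_rate=5e-5,
        planted_hotspots=[
            PlantedRegion(GenomicInterval("chr1", 100_000, 100_050), 12)
        ],
        planted_hypermut=[
            PlantedRegion(
                GenomicInterval("chr1", 50_000, 50_050), 6, 3, cohort="MALY-DE"
            )
        ],
        conserved_elements=[(GenomicInterval("chr1", 100_000, 100_050), 3.0)],
        low_mappability=[GenomicInterval("chr1", 150_000, 151_000)],
    )
    return simulate_cohort(config)
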