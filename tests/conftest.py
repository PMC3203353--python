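import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from vishotspot import ChromSizes, VISDataset, partition_genome


@pytest.fixture
def toy_genome():
    """Three small chromosomes; 1 kb bins give 10 + 5 + 3 = 18 bins."""
    return ChromSizes((("chrA", 10_000), ("chrB", 4_500), ("chrC", 2_200)))


@pytest.fixture
def toy_partition(toy_genome):
    return partition_genome(toy_genome, bin_size=1_000)


@pytest.fixture
def toy_vis(toy_genome):
    return VISDataset.from_records(
        "toy",
        toy_genome,
        [
            ("chrA", 150), ("chrA", 180), ("chrA", 220),
            ("chrA", 5_500),
            ("chrB", 1_100), ("chrB", 1_150), ("chrB", 1_190), ("chrB", 1_400),
            ("chrC", 2_100),
        ],
    )


def make_vis(genome, records, name="t"):
    return VISDataset.from_records(name, genome, records)
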