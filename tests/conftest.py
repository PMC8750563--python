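import numpy as np
import pytest

from emtchrom.intervals import GenomeModel, GenomicRegion, RegionSet
from emtchrom.synthetic import make_genome


@pytest.fixture
def toy_genome() -> GenomeModel:
    """A 100-bp single-chromosome genome with no mask."""
    return GenomeModel({"chr1": 100})


@pytest.fixture
def small_genome() -> GenomeModel:
    """A 10 Mb unmasked chromosome for placement-heavy tests."""
    return make_genome({"chr1": 10_000_000}, excluded_fraction=0.0, seed=0)


@pytest.fixture
def masked_genome() -> GenomeModel:
    """Two chromosomes, 5% masked, seeded."""
    return make_genome(
        {"chr1": 2_000_000, "chr2": 1_000_000}, excluded_fraction=0.05, seed=11
    )


def regions(*triples, label=""):
    """Shorthand RegionSet builder: regions(('chr1', 0, 100), ...)."""
    return RegionSet(
        [GenomicRegion(*t[:3], score=(t[3] if len(t) > 3 else None)) for t in triples],
        condition_label=label,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
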