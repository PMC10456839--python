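import numpy as np
import pytest

from crcsim import DiploidGenome, LocusMap


@pytest.fixture
def rng():
    return np.random.default_rng(20230825)


@pytest.fixture
def locus_map_10x2():
    """Ten chromosome pairs, two loci each (the scaled-down study genome)."""
    return LocusMap.even(10, 2)


@pytest.fixture
def het_mother(locus_map_10x2):
    return DiploidGenome.fully_heterozygous(locus_map_10x2)
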