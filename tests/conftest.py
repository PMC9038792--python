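import numpy as np
import pytest

from lohscape.genome import GenomeModel, default_genome, toy_genome
from lohscape.synthetic_data import make_snp_panel


@pytest.fixture(scope="session")
def genome() -> GenomeModel:
    return default_genome()


@pytest.fixture(scope="session")
def panel(genome):
    return make_snp_panel(genome, 3500, seed=7)


@pytest.fixture()
def tiny_genome() -> GenomeModel:
    # two 100-unit chromosomes with centromeres at 50
    return toy_genome(n_chrom=2, length=100, centromere=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
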