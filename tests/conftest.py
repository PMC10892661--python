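import pytest

from sipseek import fixtures
from sipseek.simulate import GENOTYPES, OTHER_BACTERIA, make_reference_db
from sipseek.taxonomy import train_classifier


@pytest.fixture(scope="session")
def refdb():
    """Default-divergence reference database over the genotype roster."""
    return make_reference_db(seed=101)


@pytest.fixture(scope="session")
def refdb_with_other():
    """Roster plus a pooled non-methanotroph reference, for 16S-style runs."""
    return make_reference_db(genotypes=GENOTYPES + (OTHER_BACTERIA,), seed=102)


@pytest.fixture(scope="session")
def model(refdb):
    return train_classifier(refdb)


@pytest.fixture(scope="session")
def heavy_table():
    return fixtures.heavy_fraction_table()
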