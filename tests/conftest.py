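import pytest

from cherryaphid import morpho, network, synthetic


@pytest.fixture(scope="session")
def scheme():
    return synthetic.HaplotypeScheme()


@pytest.fixture(scope="session")
def ingroup_alignment(scheme):
    """The reconstructed 51-sequence COI alignment (seed 1)."""
    return synthetic.build_alignment(scheme, seed=1)


@pytest.fixture(scope="session")
def full_alignment(ingroup_alignment, scheme):
    """In-group plus the calibrated outgroup."""
    return synthetic.add_outgroup(ingroup_alignment, seed=1, scheme=scheme)


@pytest.fixture(scope="session")
def cerasi_ids(ingroup_alignment):
    return [i for i in ingroup_alignment.ids if not i.endswith("hap5")]


@pytest.fixture(scope="session")
def borealis_ids(ingroup_alignment):
    return [i for i in ingroup_alignment.ids if i.endswith("hap5")]


@pytest.fixture(scope="session")
def haplotype_table(ingroup_alignment):
    return network.collapse_haplotypes(ingroup_alignment)


@pytest.fixture(scope="session")
def morph_table():
    """Default 50-sample cohort (380 apterae), generator default seed."""
    return synthetic.generate_morphometrics(seed=0)


@pytest.fixture(scope="session")
def train_table(morph_table):
    return morph_table[morph_table["role"] == "train"]


@pytest.fixture(scope="session")
def retained_characters(train_table):
    return morpho.correlation_filter(train_table).retained
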