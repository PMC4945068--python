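import pytest

from gutnog.annotation import build_presence_matrix
from gutnog.fixtures import load_genome_table, reference_genomes, reference_localization_profiles
from gutnog.simulate import PanGenomeScenario, generate_pangenome


@pytest.fixture(scope="session")
def genome_table():
    return load_genome_table()


@pytest.fixture(scope="session")
def ref_genomes():
    return reference_genomes()


@pytest.fixture(scope="session")
def ref_profiles():
    return reference_localization_profiles()


@pytest.fixture(scope="session")
def default_pangenome():
    """The default planted scenario (23+23 genomes, delta 12) at seed 1."""
    return generate_pangenome(PanGenomeScenario(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_pangenome):
    return build_presence_matrix(default_pangenome.assignments, default_pangenome.genomes)
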