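import pytest

from plastidcompat import fixtures
from plastidcompat.protein_analysis import variable_position_table


@pytest.fixture(scope="session")
def accd_alignment():
    return fixtures.accd_alignment()


@pytest.fixture(scope="session")
def bccp3_alignment():
    return fixtures.bccp3_alignment()


@pytest.fixture(scope="session")
def accd_table(accd_alignment):
    """accD variable-position table recomputed from the reconstructed
    alignment (not the shipped TSV)."""
    return variable_position_table(accd_alignment, fixtures.REFERENCE)


@pytest.fixture(scope="session")
def bccp3_table(bccp3_alignment):
    return variable_position_table(bccp3_alignment, fixtures.REFERENCE)


@pytest.fixture(scope="session")
def ril_fixture():
    return fixtures.paper_ril_table()
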