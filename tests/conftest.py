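import pytest

from disinfopt.dataset import expand_to_replicates, load_table1
from disinfopt.grnn import fit_grnn


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def replicates57(table1):
    return expand_to_replicates(table1)


@pytest.fixture(scope="session")
def model57(replicates57):
    """GRNN fitted on all 57 replicate observations with LOO-selected spread."""
    return fit_grnn(replicates57)
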