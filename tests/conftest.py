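import pytest

from hybridtrace import datasets


@pytest.fixture(scope="session")
def its_matrix():
    return datasets.its_variable_sites()


@pytest.fixture(scope="session")
def cp_matrix():
    return datasets.cp_variable_sites()


@pytest.fixture(scope="session")
def its_parents(its_matrix):
    """Parental ITS profiles: (cordata states, griffithii states)."""
    return its_matrix.row("CORDATA").states, its_matrix.row("GRIFFITHII").states
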