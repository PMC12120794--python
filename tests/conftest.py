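import pytest

from pmcts.fixtures import generate_fixture_corpus
from pmcts.objectives import demo_objectives
from pmcts.policy import PolicyConfig, train_policy

from tests.helpers import TokenCountObjectives


@pytest.fixture(scope="session", autouse=True)
def _quiet_rdkit():
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def corpus():
    """Canonical fixture corpus shared across the suite."""
    return generate_fixture_corpus(400, seed=0)


@pytest.fixture(scope="session")
def markov_policy(corpus):
    """Order-3 Markov policy trained on the fixture corpus."""
    return train_policy(corpus, PolicyConfig(kind="markov", order=3, seed=0))


@pytest.fixture(scope="session")
def objectives():
    """The seven-objective surrogate demo panel."""
    return demo_objectives(seed=0)


@pytest.fixture
def token_count_objectives():
    return TokenCountObjectives()
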