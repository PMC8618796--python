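import pytest

from wickerkey import fixtures
from wickerkey.key import Couplet, Lead, make_key
from wickerkey.matrix import parse_matrix


@pytest.fixture(scope="session")
def matrix():
    return fixtures.load_matrix()


@pytest.fixture(scope="session")
def key():
    return fixtures.load_key()


@pytest.fixture(scope="session")
def occurrences():
    return fixtures.load_occurrences()


@pytest.fixture(scope="session")
def mapping():
    return fixtures.load_mapping()


@pytest.fixture(scope="session")
def vocabulary():
    return fixtures.load_vocabulary()


@pytest.fixture
def toy_key():
    """Single couplet: melibiose splits two species."""
    return make_key(
        [
            Couplet(
                number=1,
                leads=(
                    Lead("a", "Mlb", "positive", target_species="Sp. alpha"),
                    Lead("b", "Mlb", "negative", target_species="Sp. beta"),
                ),
            )
        ]
    )


@pytest.fixture
def toy_matrix():
    """Three fully definite, pairwise distinct species over three characters."""
    text = (
        "species\tc1\tc2\tc3\n"
        "Sp. alpha\t+\t+\t-\n"
        "Sp. beta\t-\t+\t-\n"
        "Sp. gamma\t-\t-\t+\n"
    )
    return parse_matrix(text)
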