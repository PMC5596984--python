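from pathlib import Path

import pytest

from barcodiv import distance_matrix, make_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_data():
    """The default planted-statistics fixture (seed 1)."""
    return make_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_data):
    """Pairwise p-distance matrix of the default fixture."""
    return distance_matrix(fixture_data.alignment)


@pytest.fixture()
def holotype_path():
    return DATA_DIR / "KY777529.fasta"
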