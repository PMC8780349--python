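import pytest

from pediderm import RunConfig
from pediderm.fixtures import load_compounds, load_fixture


@pytest.fixture(scope="session")
def config():
    return RunConfig()

@pytest.fixture(scope="session")
def compounds():
    return load_compounds()

@pytest.fixture(scope="session")
def adult_rows():
    return load_fixture("adult_observations").to_dict(orient="records")

@pytest.fixture(scope="session")
def infant_rows():
    return load_fixture("infant_observations").to_dict(orient="records")
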