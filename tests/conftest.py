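import pytest

from cladediv import load_new_world_hypericum, parse_chronogram


@pytest.fixture(scope="session")
def hypericum_records():
    return load_new_world_hypericum(as_records=True)


@pytest.fixture(scope="session")
def hypericum_df():
    return load_new_world_hypericum()


@pytest.fixture
def three_tip_tree():
    return parse_chronogram("((A:1,B:1):1,C:2);")
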