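import pytest

from l1screen import load_reference_model


@pytest.fixture(scope="session")
def human():
    return load_reference_model("human")


@pytest.fixture(scope="session")
def mouse():
    return load_reference_model("mouse")
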