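import pytest

from morphocomplex.languages import build_exp1_target


@pytest.fixture(scope="session")
def target():
    return build_exp1_target()
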