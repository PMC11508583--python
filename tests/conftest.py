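import pytest

from mitocub import build_code


@pytest.fixture(scope="session")
def code5():
    """Invertebrate mitochondrial code (NCBI transl_table 5)."""
    return build_code(5)


@pytest.fixture(scope="session")
def code1():
    """Standard genetic code (NCBI transl_table 1)."""
    return build_code(1)
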