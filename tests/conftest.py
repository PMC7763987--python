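import pytest

from affecteeg.synthetic import load_table2


@pytest.fixture(scope="session")
def table2():
    """The packaged 40-participant experiment score table."""
    return load_table2()
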