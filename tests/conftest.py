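import pytest

from snpmeta import apply_hwe_filter, load_fixture

FIXTURE_NAMES = ("tgfb1_509", "tgfb1_codon10", "tgfb1_codon25")


@pytest.fixture(scope="session")
def corpora():
    """All three bundled genotype tables, unfiltered."""
    return {name: load_fixture(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def filtered(corpora):
    """The same corpora after the default control-arm HWE exclusion."""
    return {name: apply_hwe_filter(c).retained for name, c in corpora.items()}
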