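import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_record():
    """Sequence-free record of the bundled termite mitogenome annotation table."""
    from mitochar import formats

    return formats.load_reference_record()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One fully generated synthetic mitogenome plus its truth record."""
    from mitochar import synthetic

    return synthetic.generate_mitogenome(synthetic.GenomeTemplate(seed=42))
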