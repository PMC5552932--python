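import pytest

from ncyc import ErrorModel, make_reference_sets


@pytest.fixture(scope="session")
def small_refs():
    """Compact reference sets shared by unit tests (divergence-0.7 decoys)."""
    return make_reference_sets(seed=11, n_taxa_per_family=2,
                               divergence=0.7, n_background_extra=4)


@pytest.fixture
def zero_error():
    return ErrorModel(substitution_rate=0.0, indel_rate=0.0,
                      homopolymer_multiplier=1.0)
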