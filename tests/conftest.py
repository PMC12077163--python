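import pytest

from archscan.alignment import MatchAlignment
from archscan.synthetic import default_spec, sample_family


@pytest.fixture
def toy_alignment():
    """2-row, 4-column alignment: match, match, insert, match."""
    return MatchAlignment(
        ids=["r1", "r2"],
        rows=["AC.D", "AGgD"],
        col_is_match=[True, True, False, True],
    )


@pytest.fixture(scope="session")
def small_family():
    """Default-condition family, small n (shared across tests)."""
    spec = default_spec(n_sequences=120, seed=3)
    seqs, truth = sample_family(spec)
    return spec, seqs, truth


@pytest.fixture(scope="session")
def tight_family():
    """Tight-conservation family for boundary-recovery checks."""
    spec = default_spec(n_sequences=150, seed=5, tight=True)
    seqs, truth = sample_family(spec)
    return spec, seqs, truth


@pytest.fixture(scope="session")
def large_family():
    """Study-scale family (n=4999) under the default conditions."""
    spec = default_spec(n_sequences=4999, seed=17)
    seqs, truth = sample_family(spec)
    return spec, seqs, truth
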