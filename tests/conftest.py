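import pytest

from pgfam.synthetic_data import SimConfig, simulate_family_history


@pytest.fixture(scope="session")
def small_history():
    """A modest deterministic history shared by read-only tests."""
    return simulate_family_history(SimConfig(n_ancestral=10, seed=11))


@pytest.fixture()
def fresh_history():
    """A private history for tests that mutate the truth ledger."""
    return simulate_family_history(SimConfig(n_ancestral=10, seed=11))
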