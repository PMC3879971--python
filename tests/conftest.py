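import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Duplicated-CDS fixture with no substitutions and no NTP events:
    every pair is an identical duplicate (class NONE, Ks = 0)."""
    from paraloc.synthetic_data import SequenceSimParams, simulate_duplicate_sequences

    params = SequenceSimParams(
        n_families=12,
        codons_per_gene=120,
        ntp_codons=40,
        substitution_rate=0.0,
        indel_rate=0.0,
        ntp_event_probs={"none": 1.0, "partial": 0.0, "terminal": 0.0, "complete": 0.0},
        seed=11,
    )
    return params, *simulate_duplicate_sequences(params)


@pytest.fixture(scope="session")
def mixed_fixture():
    """Default mixed-noise fixture: substitutions, background indels and
    all four NTP event types."""
    from paraloc.synthetic_data import SequenceSimParams, simulate_duplicate_sequences

    params = SequenceSimParams(n_families=50, seed=7)
    return params, *simulate_duplicate_sequences(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
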