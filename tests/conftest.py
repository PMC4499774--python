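import numpy as np
import pytest

import csos2kit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_truth():
    """Default planted architecture: 4 N-repeats, TTNTTT, zero noise."""
    return ck.simulate_sequence(seed=42)


@pytest.fixture
def small_record():
    return ck.ProteinRecord(id="toy", sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")


def random_record(rng, length, rec_id="rand"):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return ck.ProteinRecord(
        id=rec_id, sequence="".join(rng.choice(alphabet, size=length))
    )
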