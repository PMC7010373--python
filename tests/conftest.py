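import random

import pytest


@pytest.fixture
def rng():
    """Deterministic RNG so randomized suites are reproducible."""
    return random.Random(20160701)
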