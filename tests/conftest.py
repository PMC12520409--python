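import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from ffhrisk import (
    GroundTruthSpec,
    load_elicited_supports,
    load_incidence_excerpt,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def excerpt():
    """The bundled 16-report excerpt of the incidence table."""
    return load_incidence_excerpt()


@pytest.fixture(scope="session")
def elicited():
    """Panel supports and published fused values for the 25 candidate edges."""
    return load_elicited_supports()


@pytest.fixture(scope="session")
def ffh21_model():
    """Ground-truth 21-node network with seeded random CPTs."""
    return make_ground_truth(GroundTruthSpec(topology="ffh21", seed=7))
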