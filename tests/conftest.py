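import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture
def conc_grid() -> np.ndarray:
    """Concentration grid typical of an EMSA titration (zero lane + 11 points)."""
    return np.concatenate([[0.0], np.geomspace(3.0, 3000.0, 11)])


@pytest.fixture
def ideal_helix():
    from sahdna import generate_helix

    return generate_helix(86)
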