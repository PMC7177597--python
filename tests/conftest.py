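import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


@pytest.fixture
def random_protein(rng):
    """Factory for random protein sequences with a chosen Cys frequency."""
    aa = np.array(list("ARNDCQEGHILKMFPSTWYV"))

    def make(length: int, cys_freq: float = 0.05) -> str:
        probs = np.full(20, (1.0 - cys_freq) / 19.0)
        probs[4] = cys_freq
        return "".join(rng.choice(aa, size=length, p=probs))

    return make
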