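import numpy as np
import pytest

from coevotriplet.msa import Alignment


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment.from_strings(["ACDEF", "ACDEF", "AWDEF", "KWDEF"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
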