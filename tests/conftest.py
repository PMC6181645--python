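import numpy as np
import pytest

from tead.library import TELibrary, TERecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def small_library(rng) -> TELibrary:
    """Three dissimilar TEs across two clades."""
    return TELibrary(
        [
            TERecord("L1HS", random_sequence(rng, 300), "non-LTR", "L1"),
            TERecord("AluY", random_sequence(rng, 280), "non-LTR", "SINE"),
            TERecord("HERVK", random_sequence(rng, 350), "LTR", "ERV2"),
        ]
    )
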