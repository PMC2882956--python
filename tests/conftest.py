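import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from nuwtscan.synthetic_data import generate_donor_panel, generate_host_panel


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


def mutate_uniform(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent re-implementation of point mutation for constructing
    fixtures (never the package's own mutator)."""
    out = list(seq)
    for i, c in enumerate(seq):
        if rng.random() < rate:
            out[i] = [b for b in "ACGT" if b != c][rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture(scope="session")
def small_donor_panel():
    return generate_donor_panel(12, 25000, seed=7)


@pytest.fixture(scope="session")
def small_host_panel():
    return generate_host_panel(4, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
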