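import numpy as np
import pandas as pd
import pytest

from chemchron import synthetic_library as syn


@pytest.fixture(scope="session")
def small_library_frame():
    """A 400-molecule synthetic library shared across tests (fixed seed)."""
    spec = syn.SyntheticLibrarySpec(n_molecules=400, seed=11)
    return syn.generate_frame(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
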