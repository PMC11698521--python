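import numpy as np
import pandas as pd
import pytest

from desim import NKConfig, NKLandscape, make_toy_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_nk():
    """Enumerable rugged landscape (64 genomes)."""
    return NKLandscape(NKConfig(n=6, k=2, a=2, landscape_seed=3))


@pytest.fixture(scope="session")
def smooth_nk():
    """Additive (K=0) landscape, single-peaked by construction."""
    return NKLandscape(NKConfig(n=12, k=0, a=2, landscape_seed=5))


@pytest.fixture(scope="session")
def toy_landscape():
    """The deceptive toy empirical landscape with its manifest."""
    return make_toy_landscape(6, 4, ruggedness_seed=0)


@pytest.fixture
def complete_table():
    """All 9 variants of a 2-site, 3-residue landscape."""
    residues = "ACD"
    rows = []
    fit = iter([0.5, 1.0, 0.2, 1.7, 0.9, 0.1, 1.3, 0.4, 2.2])
    for x in residues:
        for y in residues:
            rows.append({"sequence": x + y, "fitness": next(fit)})
    return pd.DataFrame(rows)
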