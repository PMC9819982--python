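import numpy as np
import pytest

import smoglink as sl


@pytest.fixture(scope="session")
def ring4():
    ids = ["A", "B", "C", "D"]
    pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    return sl.row_standardize(sl.build_contiguity(pairs, ids))


@pytest.fixture(scope="session")
def ring12():
    ids = [f"R{i:02d}" for i in range(12)]
    return sl.row_standardize(sl.build_contiguity(sl.ring_adjacency(12, ids), ids))


@pytest.fixture(scope="session")
def sim_default():
    """One simulated panel at the default DGP (n=30, T=13)."""
    return sl.simulate_panel(sl.DGPSpec(seed=42))


@pytest.fixture(scope="session")
def sim_small():
    """A small, fast panel for fit-level tests."""
    return sl.simulate_panel(sl.DGPSpec(n=16, T=6, seed=7))


def random_weights(rng: np.random.Generator, n: int) -> sl.SpatialWeights:
    """Random connected symmetric binary weights (ring plus chords)."""
    ids = [f"R{i:02d}" for i in range(n)]
    pairs = set(sl.ring_adjacency(n, ids))
    extra = rng.integers(0, n, size=(n // 2, 2))
    for a, b in extra:
        if a != b:
            pairs.add((ids[min(a, b)], ids[max(a, b)]))
    return sl.build_contiguity(sorted(pairs), ids)
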