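import numpy as np
import pandas as pd
import pytest

import lineagediv as L


@pytest.fixture
def toy_tree():
    """Hand-checkable 3-tip tree: ((A:1,B:1):1,C:2);"""
    return L.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest ECH synthetic study shared by read-only tests."""
    return L.make_dataset(L.SimulationConfig(n_tips=80, n_sites=40, seed=1, preset="ech"))


@pytest.fixture(scope="session")
def bd_tree():
    return L.simulate_tree(40, 1.0, 0.2, seed=12)


def random_incidence(n_sites: int, n_genera: int, seed: int, p: float = 0.3) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    inc = (rng.uniform(size=(n_sites, n_genera)) < p).astype(int)
    # guarantee >= 2 genera per site so no low_richness flags interfere
    for i in range(n_sites):
        while inc[i].sum() < 2:
            inc[i, rng.integers(n_genera)] = 1
    return pd.DataFrame(
        inc,
        index=pd.Index([f"S{i:03d}" for i in range(n_sites)], name="site_id"),
        columns=[f"G{j + 1:04d}" for j in range(n_genera)],
    )
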