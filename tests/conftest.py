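import numpy as np
import pandas as pd
import pytest

from netatrophy.datatypes import CohortParams, SpreadParams
from netatrophy.synth import make_atlas, make_cohort, make_connectome


@pytest.fixture(scope="session")
def small_atlas():
    """68-region mirror-symmetric atlas (34 per hemisphere)."""
    return make_atlas(34, seed=101)


@pytest.fixture(scope="session")
def small_connectome(small_atlas):
    return make_connectome(small_atlas, seed=102)


@pytest.fixture(scope="session")
def small_cohort(small_atlas, small_connectome):
    params = CohortParams(n_hc=40, n_pd=20)
    spread = SpreadParams(seed_regions=[0, 34], eta=0.3, n_steps=2)
    return make_cohort(small_atlas, small_connectome.sc, params, spread, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def path_graph(n=3):
    """Adjacency of a path graph 0-1-...-(n-1)."""
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return a
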