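import pathlib

import numpy as np
import pytest

from gwasconf.pop_sim import init_founders, make_next_generation, random_mating_plan

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_map_path():
    return DATA / "toy_map.tsv"


@pytest.fixture()
def rng():
    return np.random.default_rng(20240411)


def random_phased_fixture(rng, n=16, n_loci=6):
    """Small arbitrary phased cohort (not in any equilibrium)."""
    haps = (rng.random((n, 2, n_loci)) < rng.uniform(0.2, 0.8, n_loci)).astype(np.uint8)
    return haps


def random_family_fixture(rng, gmap, n=400, freqs=None):
    """One random-mating generation: (offspring, parents)."""
    L = gmap.n_loci
    if freqs is None:
        freqs = np.full(L, 0.5)
    parents = init_founders(n, freqs, rng)
    off = make_next_generation(parents, random_mating_plan(parents, rng), gmap, rng)
    return off, parents
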