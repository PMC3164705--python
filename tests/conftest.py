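import numpy as np
import pandas as pd
import pytest

from utilidiv.data import TraitTable
from utilidiv.synthetic import SyntheticConfig, generate_pool
from utilidiv.trait_space import DistanceMatrix, cluster


@pytest.fixture
def small_traits() -> TraitTable:
    """Three species with hand-checkable Gower distances."""
    frame = pd.DataFrame(
        {
            "construction": [3, 1, 0],
            "firewood": [3, 3, 0],
            "medicinal": [1, 0, 0],
            "food": [0, 1, 0],
            "tools": [0, 0, 1],
            "furniture": [0, 0, 0],
        },
        index=pd.Index(["A", "B", "C"], name="species_id"),
    )
    return TraitTable(frame)


@pytest.fixture
def three_species_dist() -> DistanceMatrix:
    """d(A,B)=0.2, d(A,C)=d(B,C)=0.6 — the hand-agglomeration case."""
    d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
    return DistanceMatrix(("A", "B", "C"), d)


@pytest.fixture
def three_species_tree(three_species_dist):
    """UPGMA tree: (A,B) merge at 0.2, ((AB),C) at 0.6."""
    return cluster(three_species_dist, "UPGMA")


@pytest.fixture(scope="session")
def pool_8():
    """Random 8-species pool and its UPGMA tree (for exhaustive FD checks)."""
    from utilidiv.trait_space import gower_distance

    cfg = SyntheticConfig(n_species=8, richness_range=(2, 8), seed=88)
    traits = generate_pool(cfg, np.random.default_rng(cfg.seed))
    tree = cluster(gower_distance(traits), "UPGMA")
    return traits, tree


@pytest.fixture(scope="session")
def pool_20_tree():
    from utilidiv.trait_space import gower_distance

    cfg = SyntheticConfig(n_species=20, richness_range=(2, 20), seed=20)
    traits = generate_pool(cfg, np.random.default_rng(cfg.seed))
    return cluster(gower_distance(traits), "UPGMA")


@pytest.fixture(scope="session")
def default_pool_tree():
    """Default 80-species pool + UPGMA tree, shared by the slower statistical tests."""
    from utilidiv.trait_space import gower_distance

    cfg = SyntheticConfig(seed=7)
    traits = generate_pool(cfg, np.random.default_rng(cfg.seed))
    dist = gower_distance(traits)
    return cfg, traits, dist, cluster(dist, "UPGMA")
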