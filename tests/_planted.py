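"""Hand-designed synthetic fixtures with planted, recoverable structure."""

import numpy as np
import pandas as pd

from utilidiv.data import CommunityMatrix, TraitTable


def importance_pool(seed: int, n: int = 40, rare_p: float = 0.1) -> TraitTable:
    """Pool where construction carries the between-cluster variation.

    Construction cycles through all four preference levels (a strong
    gradient); every other property varies only rarely (Bernoulli
    ``rare_p``), so removing construction collapses most of the trait-space
    structure while the table stays non-degenerate.
    """
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "construction": np.arange(n) % 4,
            "firewood": (rng.random(n) < rare_p).astype(int),
            "medicinal": (rng.random(n) < rare_p).astype(int),
            "food": (rng.random(n) < rare_p).astype(int),
            "tools": (rng.random(n) < rare_p).astype(int),
            "furniture": (rng.random(n) < rare_p).astype(int),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="species_id"),
    )
    return TraitTable(frame)


def random_plots(traits: TraitTable, n_plots: int, richness: int, seed: int) -> list[CommunityMatrix]:
    rng = np.random.default_rng(seed)
    return [
        CommunityMatrix(
            f"pl{i}", frozenset(rng.choice(traits.species, richness, replace=False))
        )
        for i in range(n_plots)
    ]
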