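"""Null distributions, plot evaluation, IV, property importance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from utilidiv.data import CommunityMatrix, TraitTable
from utilidiv.diversity import fd
from utilidiv.errors import DegenerateNullError, SchemaError
from utilidiv.null_model import (
    evaluate_plot,
    index_of_variance,
    null_distribution,
    null_results_frame,
    property_importance,
    run_null_model,
)
from utilidiv.synthetic import SyntheticConfig, generate_pool
from utilidiv.trait_space import cluster, gower_distance


@pytest.fixture(scope="module")
def pool_6_tree():
    cfg = SyntheticConfig(n_species=6, richness_range=(2, 6), seed=66)
    traits = generate_pool(cfg, np.random.default_rng(cfg.seed))
    return cluster(gower_distance(traits), "UPGMA")


class TestNullDistribution:
    def test_full_richness_draws_are_total_length(self, pool_6_tree):
        sample = null_distribution(pool_6_tree, 6, n_iter=50, rng=np.random.default_rng(0))
        assert np.allclose(sample, pool_6_tree.total_length)
        assert np.all(sample == sample[0])

    def test_richness_above_pool_rejected(self, pool_6_tree):
        with pytest.raises(SchemaError):
            null_distribution(pool_6_tree, 7, n_iter=10)

    def test_monte_carlo_matches_exhaustive_enumeration(self, pool_6_tree):
        # exact mean over all C(6,3)=20 subsets vs 5000 Monte-Carlo draws
        exact = np.array(
            [fd(pool_6_tree, m).fd for m in combinations(pool_6_tree.leaves, 3)]
        )
        assert len(exact) == 20
        sample = null_distribution(pool_6_tree, 3, n_iter=5000, rng=np.random.default_rng(42))
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - exact.mean()) < 3 * se

    def test_reproducible_from_seed(self, pool_6_tree):
        a = null_distribution(pool_6_tree, 3, n_iter=100, rng=np.random.default_rng(7))
        b = null_distribution(pool_6_tree, 3, n_iter=100, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestEvaluatePlot:
    def test_observed_at_null_mean_is_ns_with_zero_iv(self):
        null = np.linspace(1.0, 3.0, 999)
        res = evaluate_plot("p", null.mean(), 5, null)
        assert res.flag == "ns"
        assert res.iv == pytest.approx(0.0)

    def test_observed_above_every_draw(self):
        null = np.linspace(1.0, 3.0, 999)
        res = evaluate_plot("p", 10.0, 5, null)
        assert res.flag == "higher"
        assert res.observed_fd > res.null_q975
        assert res.p_high == pytest.approx(1 / 1000)

    def test_flag_lower_below_quantile(self):
        null = np.linspace(1.0, 3.0, 999)
        res = evaluate_plot("p", 0.5, 5, null)
        assert res.flag == "lower"
        assert res.observed_fd < res.null_q025

    def test_iv_sign_tracks_obs_vs_exp(self):
        null = np.linspace(1.0, 3.0, 999)
        assert evaluate_plot("p", 2.5, 5, null).iv > 0
        assert evaluate_plot("p", 1.5, 5, null).iv < 0


class TestIndexOfVariance:
    def test_relative_deviation_arithmetic(self):
        assert index_of_variance(2.0, 2.0) == 0.0
        assert index_of_variance(1.08 * 5.0, 5.0) == pytest.approx(0.08)

    def test_ratio_form(self):
        assert index_of_variance(3.0, 2.0, form="ratio") == pytest.approx(1.5)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(DegenerateNullError):
            index_of_variance(1.0, 0.0)


class TestRunNullModel:
    def test_bit_identical_under_fixed_seed(self, pool_6_tree):
        coms = [
            CommunityMatrix("p1", frozenset(pool_6_tree.leaves[:3])),
            CommunityMatrix("p2", frozenset(pool_6_tree.leaves[2:])),
        ]
        a = run_null_model(pool_6_tree, coms, n_iter=200, rng=np.random.default_rng(3))
        b = run_null_model(pool_6_tree, coms, n_iter=200, rng=np.random.default_rng(3))
        assert a == b
        frame = null_results_frame(a)
        assert list(frame["plot_id"]) == ["p1", "p2"]


class TestPropertyImportance:
    def test_planted_dominant_property_ranked_first(self):
        from _planted import importance_pool, random_plots

        traits = importance_pool(0)
        coms = random_plots(traits, n_plots=10, richness=12, seed=1000)
        table = property_importance(traits, coms)
        assert table.loc[table["rank"] == 1, "property"].item() == "construction"

    def test_removal_leaving_constant_table_reported_as_na(self):
        # only construction varies: removing it degenerates the Gower matrix
        frame = pd.DataFrame(
            {
                "construction": [0, 1, 2, 3] * 3,
                "firewood": 1,
                "medicinal": 0,
                "food": 1,
                "tools": 0,
                "furniture": 0,
            },
            index=pd.Index([f"s{i}" for i in range(12)], name="species_id"),
        )
        traits = TraitTable(frame)
        rng = np.random.default_rng(1)
        coms = [
            CommunityMatrix(f"p{i}", frozenset(rng.choice(traits.species, 5, replace=False)))
            for i in range(6)
        ]
        table = property_importance(traits, coms)
        assert np.isnan(table.loc[table["property"] == "construction", "fd_without"].item())
        # the degenerate removal ranks last, after all measurable drops
        assert table.loc[table["property"] == "construction", "rank"].item() == 6

    def test_constant_property_has_near_zero_drop(self, default_pool_tree):
        cfg, traits, dist, tree = default_pool_tree
        frame = traits.data.copy()
        frame["furniture"] = 0
        frame["furniture"] = frame["furniture"].astype(int)
        constant = TraitTable(frame)
        rng = np.random.default_rng(2)
        coms = [
            CommunityMatrix(f"p{i}", frozenset(rng.choice(constant.species, 12, replace=False)))
            for i in range(8)
        ]
        table = property_importance(constant, coms)
        row = table[table["property"] == "furniture"]
        # removing a constant column only renormalizes the Gower denominator
        # (6 -> 5 active columns), so the drop is a pure scale effect; ties
        # between duplicated trait profiles make the match approximate
        full = float(row["fd_all"].iloc[0])
        without = float(row["fd_without"].iloc[0])
        assert without == pytest.approx(full * 6 / 5, rel=0.02)

    def test_one_row_per_canonical_property(self, default_pool_tree):
        cfg, traits, dist, tree = default_pool_tree
        rng = np.random.default_rng(3)
        coms = [
            CommunityMatrix(f"p{i}", frozenset(rng.choice(traits.species, 10, replace=False)))
            for i in range(5)
        ]
        table = property_importance(traits, coms)
        assert len(table) == 6
        assert sorted(table["rank"]) == [1, 2, 3, 4, 5, 6]
        ranked = table.sort_values("rank")["drop"].to_numpy()
        assert all(a >= b or np.isnan(b) for a, b in zip(ranked, ranked[1:]))
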