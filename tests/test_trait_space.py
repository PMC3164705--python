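"""Gower distances, linkage selection, cophenetic correlation, Newick export."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utilidiv.data import TraitTable
from utilidiv.errors import (
    DegenerateDistanceError,
    SchemaError,
    UndefinedCorrelationError,
)
from utilidiv.synthetic import SyntheticConfig, generate_pool
from utilidiv.trait_space import (
    DEFAULT_LINKAGE_CANDIDATES,
    DistanceMatrix,
    cluster,
    cophenetic_correlation,
    gower_distance,
    select_linkage,
    to_newick,
)


def _table(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return TraitTable(
        pd.DataFrame(
            rows,
            columns=["construction", "firewood", "medicinal", "food", "tools", "furniture"],
            index=pd.Index(ids, name="species_id"),
        )
    )


class TestGower:
    def test_identical_species_distance_zero(self):
        t = _table([[3, 3, 1, 0, 0, 0], [3, 3, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        d = gower_distance(t)
        assert d.values[0, 1] == 0.0

    def test_maximally_different_species_distance_one(self):
        t = _table([[3, 3, 1, 1, 1, 1], [0, 0, 0, 0, 0, 0]])
        d = gower_distance(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_mixed_case(self):
        # A=(3,3,1,0,0,0), B=(1,3,0,1,0,0); ordinal ranges over pool are 3
        # d = (2/3 + 0 + 1 + 1 + 0 + 0) / 6
        t = _table([[3, 3, 1, 0, 0, 0], [1, 3, 0, 1, 0, 0], [0, 0, 0, 0, 0, 0]], ["A", "B", "C"])
        d = gower_distance(t)
        assert d.values[0, 1] == pytest.approx((2 / 3 + 0 + 1 + 1) / 6)

    def test_zero_range_property_contributes_zero_but_stays_in_denominator(self):
        # firewood constant: only construction differs (by 2 of range 2)
        t = _table([[2, 1, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0]])
        d = gower_distance(t)
        assert d.values[0, 1] == pytest.approx(1 / 6)

    def test_all_constant_table_degenerate(self):
        t = _table([[1, 1, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0]])
        with pytest.raises(DegenerateDistanceError):
            gower_distance(t)

    def test_weights_shift_distance(self):
        t = _table([[3, 0, 1, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
        unweighted = gower_distance(t).values[0, 1]
        heavy = gower_distance(t, weights={"construction": 5.0}).values[0, 1]
        assert heavy > unweighted

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12))
    def test_metric_identity_symmetry_bounds(self, seed, n):
        cfg = SyntheticConfig(n_species=n, richness_range=(1, n), seed=seed)
        traits = generate_pool(cfg, np.random.default_rng(seed))
        d = gower_distance(traits).values
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1 + 1e-12


class TestCluster:
    def test_hand_agglomeration_upgma(self, three_species_dist):
        tree = cluster(three_species_dist, "UPGMA")
        assert tree.heights == pytest.approx([0.2, 0.6])
        first = {tree.leaves[i] for i in tree.merges[0]}
        assert first == {"A", "B"}

    def test_two_species_single_merge(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = cluster(d, "UPGMA")
        assert tree.heights == pytest.approx([0.4])
        assert tree.total_length == pytest.approx(0.8)

    def test_permutation_invariance_of_cophenetic_distances(self):
        # tie-free distances: agglomeration order is unambiguous, so the
        # tree must be identical up to relabeling
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(1)
        n = 20
        d = squareform(rng.uniform(0.05, 1.0, n * (n - 1) // 2))
        labels = tuple(f"x{i}" for i in range(n))
        dist = DistanceMatrix(labels, d)
        perm = rng.permutation(n)
        permuted = DistanceMatrix(
            tuple(labels[i] for i in perm), d[np.ix_(perm, perm)]
        )
        coph_a = squareform(cluster(dist, "UPGMA").cophenetic_matrix())
        coph_b = squareform(cluster(permuted, "UPGMA").cophenetic_matrix())
        inv = np.argsort(perm)
        assert np.allclose(coph_a, coph_b[np.ix_(inv, inv)])

    def test_unknown_method_rejected(self, three_species_dist):
        with pytest.raises(SchemaError):
            cluster(three_species_dist, "centroid")

    def test_single_linkage_cophenetic_distances_are_minimal(self):
        # single linkage gives the subdominant ultrametric: its cophenetic
        # distances never exceed UPGMA's (and never exceed the input)
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(2)
        n = 18
        v = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
        dist = DistanceMatrix(tuple(f"x{i}" for i in range(n)), squareform(v))
        coph_single = cluster(dist, "single").cophenetic_matrix()
        coph_upgma = cluster(dist, "UPGMA").cophenetic_matrix()
        assert np.all(coph_single <= coph_upgma + 1e-12)
        assert np.all(coph_single <= v + 1e-12)


class TestCopheneticCorrelation:
    def test_ultrametric_input_reproduced_exactly(self, three_species_dist):
        tree = cluster(three_species_dist, "UPGMA")
        assert cophenetic_correlation(tree, three_species_dist) == pytest.approx(1.0)
        coph = tree.cophenetic_matrix()
        assert np.allclose(sorted(coph), [0.2, 0.6, 0.6])

    def test_non_ultrametric_input_correlation_below_one(self):
        # 4 points where no ultrametric tree can reproduce the distances
        d = np.array(
            [
                [0.0, 0.1, 0.5, 0.9],
                [0.1, 0.0, 0.9, 0.5],
                [0.5, 0.9, 0.0, 0.1],
                [0.9, 0.5, 0.1, 0.0],
            ]
        )
        dist = DistanceMatrix(("A", "B", "C", "D"), d)
        tree = cluster(dist, "UPGMA")
        assert cophenetic_correlation(tree, dist) < 1.0

    def test_fewer_than_three_species_undefined(self):
        dist = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = cluster(dist, "UPGMA")
        with pytest.raises(UndefinedCorrelationError):
            cophenetic_correlation(tree, dist)


class TestSelectLinkage:
    def test_ultrametric_ties_broken_toward_upgma(self, three_species_dist):
        tree, report = select_linkage(three_species_dist)
        assert tree.linkage_method == "UPGMA"
        assert tree.cophenetic_r == pytest.approx(1.0)
        assert np.allclose(report["cophenetic_r"], 1.0)

    def test_winner_dominates_and_report_covers_all_methods(self, default_pool_tree):
        _, _, dist, _ = default_pool_tree
        tree, report = select_linkage(dist)
        assert set(report["method"]) == set(DEFAULT_LINKAGE_CANDIDATES)
        assert len(report) == len(DEFAULT_LINKAGE_CANDIDATES)
        assert tree.cophenetic_r >= report["cophenetic_r"].max() - 1e-12

    def test_needs_two_candidates(self, three_species_dist):
        with pytest.raises(SchemaError):
            select_linkage(three_species_dist, methods=("UPGMA",))


class TestNewick:
    def test_two_species_string(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert to_newick(cluster(d, "UPGMA")) == "(A:0.4,B:0.4);"

    def test_three_species_edge_lengths(self, three_species_tree):
        nwk = to_newick(three_species_tree)
        assert nwk == "((A:0.2,B:0.2):0.4,C:0.6);"

    def test_roundtrip_preserves_patristic_distances(self, default_pool_tree):
        # parse with an independent Newick reader; tip-to-tip path length in
        # the tree equals twice the cophenetic merge height
        _, _, dist, tree = default_pool_tree
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        from scipy.spatial.distance import squareform

        coph = squareform(tree.cophenetic_matrix())
        labels = tree.leaves
        for i in range(0, len(labels), 7):  # spot-check a grid of pairs
            for j in range(i + 1, len(labels), 11):
                got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(2 * coph[i, j], abs=1e-9)
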