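import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dendropy

from scsc import (
    BinaryCodeTable,
    DegenerateSplitError,
    InputError,
    assign_codes,
    bifurcate_scalar_field,
    build_dendrogram,
    converged_clusters,
    solve_coloring,
)
from conftest import hierarchical_block_adjacency


def coded_tree(A, depth):
    sol = solve_coloring(A)
    codes = assign_codes(sol, depth)
    return sol, codes, build_dendrogram(codes, sol, A)


class TestBifurcation:
    def test_four_point_average_linkage_oracle(self):
        labels = bifurcate_scalar_field(np.array([0.0, 0.01, 10.0, 10.02]))
        assert labels[0] == labels[1] != labels[2] == labels[3]
        # polarity: equal sizes, lower-mean group gets bit 0
        assert labels[0] == 0

    def test_constant_field_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            bifurcate_scalar_field(np.full(6, 3.3))

    @given(
        values=st.lists(
            st.floats(-100, 100, allow_nan=False, width=32),
            min_size=2,
            max_size=40,
            unique=True,
        ),
        shift=st.floats(-50, 50, allow_nan=False, width=32),
    )
    def test_negation_and_shift_invariance(self, values, shift):
        x = np.asarray(values)
        base = bifurcate_scalar_field(x)
        flipped = bifurcate_scalar_field(-x)
        shifted = bifurcate_scalar_field(x + shift)
        assert np.array_equal(base, flipped) or np.array_equal(base, 1 - flipped)
        assert np.array_equal(base, shifted) or np.array_equal(base, 1 - shifted)

    def test_two_separated_modes_cut_between_them(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-3, 0.5, 120), rng.normal(3, 0.5, 80)])
        labels = bifurcate_scalar_field(x)
        assert np.array_equal(labels, (x > 0).astype(np.uint8))

    def test_featureless_field_sheds_small_splinter(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        labels = bifurcate_scalar_field(x)
        assert 0 < labels.sum() < 0.05 * x.size

    def test_conditional_mode_detection(self):
        # bimodality confined to the first group, invisible globally
        rng = np.random.default_rng(2)
        grp0 = np.concatenate([rng.normal(-1, 0.1, 100), rng.normal(1, 0.1, 100)])
        grp1 = rng.normal(0, 1.2, 200)
        x = np.concatenate([grp0, grp1])
        groups = np.repeat([0, 1], 200)
        labels = bifurcate_scalar_field(x, groups=groups)
        first = labels[:200]
        assert np.array_equal(first, (grp0 > 0).astype(np.uint8)) or np.array_equal(
            first, (grp0 < 0).astype(np.uint8)
        )

    def test_parameter_validation(self):
        x = np.arange(30.0)
        with pytest.raises(InputError):
            bifurcate_scalar_field(x, min_mode_frac=0.7)
        with pytest.raises(InputError):
            bifurcate_scalar_field(x, valley_ratio=0.0)
        with pytest.raises(InputError):
            bifurcate_scalar_field(np.array([1.0, np.inf]))


class TestAssignCodes:
    def test_two_states_get_distinct_single_bits(self, pair_adjacency):
        sol = solve_coloring(pair_adjacency)
        codes = assign_codes(sol, depth=1)
        assert sorted(codes.strings) == ["0", "1"]

    def test_depth_bounds(self, triangle_adjacency):
        sol = solve_coloring(triangle_adjacency)
        with pytest.raises(InputError):
            assign_codes(sol, 0)
        with pytest.raises(InputError):
            assign_codes(sol, 3)  # constant mode may not be used

    @given(seed=st.integers(0, 30))
    def test_occupied_codes_bounded_and_refining(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((12, 12))
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        from scsc import AdjacencyMatrix

        sol = solve_coloring(AdjacencyMatrix(values))
        codes = assign_codes(sol, depth=5)
        previous = None
        for depth in range(1, 6):
            occupied = codes.occupied(depth)
            assert len(occupied) <= min(2**depth, 12)
            if previous is not None:
                # monotone refinement: every code extends a previous one
                assert {c[:-1] for c in occupied} <= set(previous)
            previous = occupied

    def test_code_table_validation(self):
        with pytest.raises(InputError):
            BinaryCodeTable(codes=np.array([[0, 2]]), depth=2)
        with pytest.raises(InputError):
            BinaryCodeTable(codes=np.zeros((3, 2), dtype=np.uint8), depth=3)


class TestDendrogram:
    def test_first_branch_pair_length_is_top_eigenvalue(self, block_adjacency):
        A, _ = block_adjacency
        sol, codes, tree = coded_tree(A, depth=3)
        for child in tree.root.children:
            assert child.branch_length == pytest.approx(sol.eigenvalues[0], abs=1e-8)

    def test_member_conservation_and_widths(self, block_adjacency):
        A, _ = block_adjacency
        _, _, tree = coded_tree(A, depth=3)
        for node in tree.nodes.values():
            if len(node.children) == 2:
                assert sum(c.count for c in node.children) == node.count
            elif len(node.children) == 1:  # pass-through keeps the member set
                assert node.children[0].count == node.count
            assert node.width == pytest.approx(node.count / tree.n)

    def test_planted_blocks_converge_to_four_leaves_by_depth_two(
        self, block_adjacency
    ):
        A, labels = block_adjacency
        _, _, tree = coded_tree(A, depth=4)
        leaves = tree.leaves()
        big = [nd for nd in leaves if nd.count >= 5]
        assert len(big) == 4
        for nd in big:
            assert nd.creation_level <= 2
            assert np.unique(labels[nd.members]).size == 1

    def test_bit_flip_leaves_structure_invariant(self, block_adjacency):
        A, _ = block_adjacency
        sol = solve_coloring(A)
        codes = assign_codes(sol, 3)
        flipped = BinaryCodeTable(
            codes.codes ^ np.array([0, 1, 0], dtype=np.uint8), depth=3
        )
        t1 = build_dendrogram(codes, sol, A)
        t2 = build_dendrogram(flipped, sol, A)
        sets1 = {frozenset(nd.members.tolist()) for nd in t1.leaves()}
        sets2 = {frozenset(nd.members.tolist()) for nd in t2.leaves()}
        assert sets1 == sets2
        lens1 = sorted(round(nd.branch_length, 9) for nd in t1.nodes.values())
        lens2 = sorted(round(nd.branch_length, 9) for nd in t2.nodes.values())
        assert lens1 == lens2

    def test_singleton_passthrough_has_zero_length(self, pair_adjacency):
        # depth 1 on two states: each leaf is a singleton at level 1
        sol, codes, tree = coded_tree(pair_adjacency, depth=1)
        for leaf in tree.leaves():
            assert leaf.count == 1

    def test_min_branch_z_suppresses_weak_splits(self, block_adjacency):
        A, _ = block_adjacency
        sol = solve_coloring(A)
        codes = assign_codes(sol, 3)
        tree = build_dendrogram(codes, sol, A, min_branch_z=1e9)
        assert len(tree.leaves()) == 1
        assert tree.leaves()[0].count == A.n

    def test_newick_round_trip_through_dendropy(self, block_adjacency):
        A, _ = block_adjacency
        _, _, tree = coded_tree(A, depth=3)
        loaded = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(loaded.leaf_nodes()) == len(tree.leaves())
        lengths = sorted(
            e.length for e in loaded.preorder_edge_iter() if e.length is not None
        )
        expected = sorted(nd.branch_length for nd in tree.nodes.values() if nd.prefix)
        np.testing.assert_allclose(lengths[-len(expected):], expected, rtol=1e-6)


class TestConvergedClusters:
    def test_partition_properties(self, block_adjacency):
        A, _ = block_adjacency
        _, _, tree = coded_tree(A, depth=4)
        clusters = converged_clusters(tree)
        all_members = np.concatenate(clusters)
        assert np.array_equal(np.sort(all_members), np.arange(A.n))

    def test_planted_blocks_recovered_at_depth_four(self, block_adjacency):
        A, labels = block_adjacency
        _, _, tree = coded_tree(A, depth=4)
        clusters = [c for c in converged_clusters(tree) if c.size >= 5]
        assert len(clusters) == 4
        recovered = {frozenset(c.tolist()) for c in clusters}
        truth = {frozenset(np.flatnonzero(labels == b).tolist()) for b in range(4)}
        # allow tiny splinters: every true block is the superset of one cluster
        for cluster in recovered:
            assert any(cluster <= block for block in truth)

    def test_depth_beyond_tree_errors(self, block_adjacency):
        A, _ = block_adjacency
        _, _, tree = coded_tree(A, depth=2)
        with pytest.raises(InputError):
            converged_clusters(tree, depth=5)
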