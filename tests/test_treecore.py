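"""Tree model, Newick round-trips, constructors, enumeration, classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthvar.treecore import (
    CandidateType,
    DepthMultiset,
    DuplicateLabelError,
    NewickError,
    TreeShape,
    UnaryNodeError,
    UnrealizableDepthsError,
    balanced_class_predicates,
    build_classic,
    classify_type,
    count_shapes,
    depth_multiset,
    enumerate_shapes,
    is_maximally_balanced,
    odd_double_factorial,
    parse_newick,
    parse_newick_many,
    random_tree,
    shape_of,
    tree_from_depths,
    write_newick,
)


# ---------------------------------------------------------------------------
# Newick I/O


class TestParseNewick:
    def test_three_leaf_caterpillar(self):
        t = parse_newick("((a,b),c);")
        assert t.shape == build_classic("comb", 3)
        assert depth_multiset(t) == DepthMultiset({1: 1, 2: 2})

    def test_multifurcation_preserved(self):
        t = parse_newick("(a,b,c,d);")
        assert t.shape == build_classic("star", 4)
        assert depth_multiset(t) == DepthMultiset({1: 4})

    def test_branch_lengths_and_internal_labels_ignored(self):
        assert parse_newick("((a:1,b:2)x:3,c:4);").shape == parse_newick("((a,b),c);").shape

    def test_unlabeled_leaves_get_fresh_labels(self):
        t = parse_newick("((,),c);")
        assert len(set(t.labels)) == 3

    def test_malformed_input_raises_with_position(self):
        with pytest.raises(NewickError, match=r"column"):
            parse_newick("((a,b;")

    def test_unary_node_rejected_by_default(self):
        with pytest.raises(UnaryNodeError):
            parse_newick("((a)x,b);")

    def test_unary_node_collapse_flag(self):
        t = parse_newick("((a)x,b);", collapse_unary=True)
        assert t.shape == build_classic("star", 2)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DuplicateLabelError):
            parse_newick("((a,a),b);")

    def test_multi_tree_document(self):
        trees = parse_newick_many("# header\n(a,b);\n((a,b),c);\n")
        assert [t.n for t in trees] == [2, 3]


class TestWriteNewick:
    @pytest.mark.parametrize(
        "text",
        ["((a,b),c);", "(a,b,c);", "((a,b),(c,d));", "(((x,y),(u,v)),((p,q),(r,s)));"],
    )
    def test_round_trip_preserves_shape_and_labels(self, text):
        t = parse_newick(text)
        back = parse_newick(write_newick(t))
        assert back.shape == t.shape
        assert sorted(map(str, back.labels)) == sorted(map(str, t.labels))

    def test_canonical_rendering_is_label_order_independent(self):
        assert write_newick(parse_newick("(b,a,c);")) == write_newick(parse_newick("(c,a,b);"))

    def test_quoting_labels_with_special_characters(self):
        t = parse_newick(write_newick(parse_newick("('a b','c(d');")))
        assert sorted(t.labels) == ["a b", "c(d"]


def test_shape_of_forgets_labels():
    a = parse_newick("(((a,b),c),d);")
    b = parse_newick("(((d,c),b),a);")
    assert shape_of(a) == shape_of(b) == build_classic("comb", 4)
    assert shape_of(parse_newick("((a,b),(c,d));")) != build_classic("comb", 4)


# ---------------------------------------------------------------------------
# constructors and depth multisets


class TestBuildClassic:
    def test_comb_depths(self):
        # all leaves at distinct depths except the deepest cherry
        assert depth_multiset(build_classic("comb", 8)) == DepthMultiset(
            {1: 1, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1, 7: 2}
        )

    def test_b8_is_fully_symmetric(self):
        b8 = build_classic("max_balanced", 8)
        assert b8 == build_classic("fully_symmetric", 8)
        assert depth_multiset(b8) == DepthMultiset({3: 8})

    def test_b6_depths(self):
        assert depth_multiset(build_classic("max_balanced", 6)) == DepthMultiset({2: 2, 3: 4})

    def test_f_type_depths(self):
        # n = 6 = 2^2 + 2: 2k = 4 leaves at depth 3, 2^m - k = 2 leaves at depth 2
        assert depth_multiset(build_classic("f_type", 6)) == DepthMultiset({2: 2, 3: 4})

    def test_star_depths(self):
        assert depth_multiset(build_classic("star", 7)) == DepthMultiset({1: 7})

    def test_comb_sackin(self):
        # S(K_n) = (n-1)(n+2)/2
        d = depth_multiset(build_classic("comb", 3))
        assert sum(depth * c for depth, c in d.items()) == 5

    def test_fully_symmetric_requires_power_of_two(self):
        with pytest.raises(ValueError):
            build_classic("fully_symmetric", 6)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            build_classic("comb", 0)

    def test_unary_shape_construction_rejected(self):
        with pytest.raises(UnaryNodeError):
            TreeShape([TreeShape()])


class TestTreeFromDepths:
    def test_unique_three_leaf_shape(self):
        assert tree_from_depths(DepthMultiset([1, 2, 2])) == build_classic("comb", 3)

    def test_b6_class_representative(self):
        d = DepthMultiset({2: 2, 3: 4})
        assert depth_multiset(tree_from_depths(d)) == d

    def test_infeasible_multiset_reports_kraft_sum(self):
        with pytest.raises(UnrealizableDepthsError, match="5/4"):
            tree_from_depths(DepthMultiset([1, 1, 2]))

    def test_single_leaf(self):
        assert tree_from_depths(DepthMultiset({0: 1})).is_leaf

    @pytest.mark.parametrize("n", [5, 11, 24, 64, 100])
    def test_round_trip_on_random_bifurcating_shapes(self, n):
        for seed in range(3):
            d = depth_multiset(random_tree(n, "bifurcating", seed))
            assert d.kraft_sum() == 1
            assert depth_multiset(tree_from_depths(d)) == d


# ---------------------------------------------------------------------------
# enumeration


class TestEnumeration:
    def test_four_leaves(self):
        shapes = dict(enumerate_shapes(4))
        assert len(shapes) == 2
        assert shapes[build_classic("comb", 4)] == 12
        assert shapes[build_classic("max_balanced", 4)] == 3
        assert sum(shapes.values()) == 15 == odd_double_factorial(5)

    def test_six_leaves(self):
        shapes = list(enumerate_shapes(6))
        assert len(shapes) == 6
        assert sum(c for _, c in shapes) == 945

    def test_two_leaves(self):
        assert list(enumerate_shapes(2)) == [(build_classic("max_balanced", 2), 1)]

    @pytest.mark.parametrize("n", range(2, 13))
    def test_labeled_counts_sum_to_double_factorial(self, n, shapes_by_n):
        assert sum(c for _, c in shapes_by_n(n)) == odd_double_factorial(2 * n - 3)

    def test_shapes_are_distinct(self, shapes_by_n):
        for n in (7, 9):
            shapes = [s for s, _ in shapes_by_n(n)]
            assert len(set(shapes)) == len(shapes)

    @pytest.mark.parametrize("n", range(2, 12))
    def test_maximally_balanced_tree_is_unique(self, n, shapes_by_n):
        hits = [s for s, _ in shapes_by_n(n) if is_maximally_balanced(s)]
        assert hits == [build_classic("max_balanced", n)]

    def test_wedderburn_etherington_counts(self):
        assert [count_shapes(n) for n in range(1, 11)] == [1, 1, 1, 2, 3, 6, 11, 23, 46, 98]


# ---------------------------------------------------------------------------
# random fixtures


class TestRandomTree:
    def test_deterministic_for_fixed_seed(self):
        assert random_tree(5, "bifurcating", 1) == random_tree(5, "bifurcating", 1)
        assert random_tree(30, "multifurcating", 9) == random_tree(30, "multifurcating", 9)

    def test_single_leaf(self):
        assert random_tree(1, "bifurcating", 3).is_leaf

    def test_bifurcating_mode(self):
        assert random_tree(40, "bifurcating", 2).is_bifurcating()

    def test_multifurcations_occur(self):
        shapes = [random_tree(30, "multifurcating", s) for s in range(5)]
        assert any(
            len(v.children) >= 3 for s in shapes for v in s.iter_nodes()
        )


# ---------------------------------------------------------------------------
# classification


class TestClassifyType:
    def test_184_leaf_minimizer(self):
        shape = tree_from_depths(DepthMultiset({8: 174, 7: 9, 2: 1}))
        assert classify_type(shape) == CandidateType(184, (6,))

    def test_b6_is_empty_type(self):
        assert classify_type(build_classic("max_balanced", 6)) == CandidateType(6, ())

    def test_comb_is_no_type(self):
        # combs with n >= 4 have a depth-1 leaf, which candidate types exclude
        assert classify_type(build_classic("comb", 8)) is None

    def test_multifurcating_rejected(self):
        with pytest.raises(ValueError):
            classify_type(build_classic("star", 4))

    @pytest.mark.parametrize("n", range(1, 10))
    def test_four_characterizations_coincide(self, n, shapes_by_n):
        for shape, _ in shapes_by_n(n):
            preds = balanced_class_predicates(shape)
            assert len(set(preds)) == 1, (n, shape, preds)


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=60, derandomize=True, deadline=None)
@given(n=st.integers(2, 40), seed=st.integers(0, 10**6))
def test_depth_multiset_of_bifurcating_tree_is_kraft_tight(n, seed):
    d = depth_multiset(random_tree(n, "bifurcating", seed))
    assert d.kraft_sum() == 1
    assert d.n == n


@settings(max_examples=60, derandomize=True, deadline=None)
@given(n=st.integers(1, 30), seed=st.integers(0, 10**6))
def test_tree_from_depths_preserves_depth_multiset(n, seed):
    d = depth_multiset(random_tree(n, "bifurcating", seed))
    assert depth_multiset(tree_from_depths(d)) == d


@settings(max_examples=40, derandomize=True, deadline=None)
@given(n=st.integers(2, 25), seed=st.integers(0, 10**6))
def test_shape_equality_is_label_and_order_insensitive(n, seed):
    shape = random_tree(n, "multifurcating", seed)
    mirrored = TreeShape(tuple(reversed(shape.children))) if shape.children else shape
    assert mirrored == shape
    assert hash(mirrored) == hash(shape)
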