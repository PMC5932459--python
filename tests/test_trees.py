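"""Tree structures, canonical forms, splits, forgetful maps, enumeration."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from alphatree.probability import double_factorial
from alphatree.trees import (
    Cladogram,
    NewickParseError,
    Node,
    OrderedCladogram,
    OrderedTreeShape,
    TreeShape,
    enumerate_cladograms,
    enumerate_shapes,
    forget_labels,
    forget_order,
    parse_newick,
    preimage_count,
    root_join,
    shape_of,
)

from conftest import EXAMPLE7_NEWICK, COUNTEREXAMPLE8_NEWICK

WEDDERBURN_ETHERINGTON = [1, 1, 1, 2, 3, 6, 11, 23, 46, 98]


def random_ordered_cladogram(n: int, rng: np.random.Generator) -> OrderedCladogram:
    """Uniform-ish random ordered cladogram for property tests."""
    labels = [str(i) for i in range(1, n + 1)]
    rng.shuffle(labels)
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=(a, b)))
    return OrderedCladogram(nodes[0])


class TestParsing:
    @pytest.mark.parametrize(
        "text,mode,n",
        [
            ("(1,2);", "cladogram", 2),
            ("((,),);", "shape", 3),
            (EXAMPLE7_NEWICK, "cladogram", 7),
            (COUNTEREXAMPLE8_NEWICK, "cladogram", 8),
            ("(((,),),(,));", "shape", 5),
        ],
    )
    def test_leaf_counts(self, text, mode, n):
        assert parse_newick(text, mode).n_leaves == n

    def test_semicolon_optional_on_input(self):
        assert parse_newick("(1,2)", "cladogram") == parse_newick("(1,2);", "cladogram")

    @pytest.mark.parametrize(
        "text,mode",
        [
            ("((1,2,3),4);", "cladogram"),  # non-binary
            ("((1,2),(1,3));", "cladogram"),  # duplicate label
            ("((1,2),);", "cladogram"),  # unlabeled leaf in cladogram mode
            ("((1:0.1,2),3);", "cladogram"),  # branch lengths out of dialect
            ("((1,2", "cladogram"),  # malformed
        ],
    )
    def test_rejects_out_of_dialect(self, text, mode):
        with pytest.raises(NewickParseError):
            parse_newick(text, mode)

    def test_write_parse_round_trip(self):
        fixtures = [
            ("(1,2);", "cladogram"),
            (EXAMPLE7_NEWICK, "cladogram"),
            (COUNTEREXAMPLE8_NEWICK, "cladogram"),
            ("((,),(,(,)));", "shape"),
            ("((2,1),(4,3));", "ordered-cladogram"),
            ("((,),(,(,)));", "ordered-shape"),
        ]
        for text, mode in fixtures:
            t = parse_newick(text, mode)
            assert parse_newick(t.newick, mode) == t

    def test_canonical_order_balanced_subtree_first(self, counterexample8):
        assert counterexample8.newick == "(((1,2),(3,4)),(8,(7,(5,6))));"


class TestKappaAndSplits:
    def test_kappa_root_and_leaves(self, example7):
        assert example7.kappa(example7.root) == 7
        for leaf in example7.leaves():
            assert example7.kappa(leaf) == 1

    def test_kappa_of_inner_node(self, example7):
        # the (4,5)-split node of the 5-leaf subtree covers leaves 4..7
        [node] = [v for v in example7.internal_nodes() if v.n_leaves == 4]
        assert example7.kappa(node) == 4

    def test_kappa_rejects_foreign_node(self, example7):
        with pytest.raises(ValueError):
            example7.kappa(Node(label="99"))

    def test_split_multisets(self, example7):
        assert example7.numerical_splits() == [(1, 1), (1, 1), (1, 1), (2, 2), (1, 4), (2, 5)]
        assert parse_newick("(1,2);", "cladogram").numerical_splits() == [(1, 1)]
        cat4 = parse_newick("(((1,2),3),4);", "cladogram")
        assert cat4.numerical_splits() == [(1, 3), (1, 2), (1, 1)]

    def test_unordered_split_is_min_max_of_ordered(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            oc = random_ordered_cladogram(int(rng.integers(2, 10)), rng)
            unordered = forget_order(oc).numerical_splits()
            assert unordered == [tuple(sorted(s)) for s in oc.ordered_splits()]


class TestSymmetricBranchPoints:
    @pytest.mark.parametrize(
        "text,k",
        [
            ("(1,2);", 1),
            (COUNTEREXAMPLE8_NEWICK, 4),  # three cherries + the (2,2) node; root is NOT symmetric
            (EXAMPLE7_NEWICK, 4),
        ],
    )
    def test_counts(self, text, k):
        assert parse_newick(text, "cladogram").symmetric_branch_count() == k


class TestForgetfulMaps:
    def test_same_shape_different_labelings(self):
        a = parse_newick("(((1,2),3),(4,5));", "cladogram")
        b = parse_newick("(((5,3),4),(1,2));", "cladogram")
        assert a != b
        assert shape_of(a) == shape_of(b)

    def test_commuting_square(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            oc = random_ordered_cladogram(8, rng)
            assert forget_order(forget_labels(oc)) == forget_labels(forget_order(oc)) == shape_of(oc)


def all_orderings(shape: TreeShape):
    """Brute-force: every ordered tuple-tree refining an unordered shape."""

    def rec(node):
        if node.is_leaf:
            yield Node()
            return
        a, b = node.children
        for x, y in itertools.product(rec(a), rec(b)):
            yield Node(children=(x, y))
            yield Node(children=(y, x))

    return {OrderedTreeShape(r) for r in rec(shape.root)}


class TestPreimageCounts:
    @pytest.mark.parametrize("n", range(2, 7))
    def test_pi_formula_vs_exhaustive_labeling(self, n):
        by_shape = {}
        for t in enumerate_cladograms(n):
            by_shape.setdefault(t.shape(), 0)
            by_shape[t.shape()] += 1
        for s, count in by_shape.items():
            assert preimage_count(s, "pi") == count

    @pytest.mark.parametrize("n", range(2, 7))
    def test_pi_os_formula_vs_exhaustive_ordering(self, n):
        for s in enumerate_shapes(n):
            assert preimage_count(s, "pi_os") == len(all_orderings(s))

    def test_fixed_values(self, counterexample8, example7):
        s = counterexample8.shape()
        assert preimage_count(s, "pi") == math.factorial(8) // 2**4 == 2520
        assert preimage_count(s, "pi_os") == 2 ** (8 - 1 - 4) == 8
        assert preimage_count(example7, "pi_o") == 2**6 == 64

    def test_partition_of_cladograms_by_shape(self):
        # Σ over n-leaf shapes of n!/2^k = (2n−3)!!
        for n in range(2, 9):
            total = sum(preimage_count(s, "pi") for s in enumerate_shapes(n))
            assert total == double_factorial(2 * n - 3)


class TestRootJoin:
    def test_leaf_join_is_cherry(self):
        cherry = root_join(
            Cladogram(Node(label="1")), Cladogram(Node(label="2"))
        )
        assert cherry == parse_newick("(1,2);", "cladogram")

    def test_counterexample_shape_construction(self, counterexample8):
        bal4 = parse_newick("((,),(,));", "shape")
        cat4 = parse_newick("(((,),),);", "shape")
        assert root_join(bal4, cat4) == counterexample8.shape()

    def test_split_multiset_is_additive(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = forget_order(random_ordered_cladogram(int(rng.integers(2, 6)), rng))
            brs = random_ordered_cladogram(int(rng.integers(2, 6)), rng)
            b = forget_order(OrderedCladogram(_relabel(brs.root, offset=10)))
            joined = root_join(a, b)
            expect = list(a.numerical_splits()) + list(b.numerical_splits())
            expect.append(tuple(sorted((a.n_leaves, b.n_leaves))))
            assert joined.numerical_splits() == expect

    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError):
            root_join(parse_newick("(1,2);", "cladogram"), parse_newick("(2,3);", "cladogram"))


def _relabel(node: Node, offset: int) -> Node:
    if node.is_leaf:
        return Node(label=str(int(node.label) + offset))
    return Node(children=tuple(_relabel(c, offset) for c in node.children))


class TestEnumeration:
    @pytest.mark.parametrize("n", range(1, 11))
    def test_shape_counts_are_wedderburn_etherington(self, n):
        shapes = enumerate_shapes(n)
        assert len(shapes) == len(set(shapes)) == WEDDERBURN_ETHERINGTON[n - 1]

    @pytest.mark.parametrize("n", range(1, 8))
    def test_cladogram_counts_are_double_factorial(self, n):
        cl = enumerate_cladograms(n)
        assert len(cl) == len(set(cl)) == double_factorial(2 * n - 3)

    def test_cladogram_structural_invariants(self):
        for t in enumerate_cladograms(6):
            ns = list(t.numerical_splits())
            assert len(ns) == 5
            assert sum(max(ns, key=lambda s: s[0] + s[1])) == 6

    def test_range_errors(self):
        with pytest.raises(ValueError):
            enumerate_cladograms(9)
        with pytest.raises(ValueError):
            enumerate_shapes(0)


def brute_force_isomorphic(a: Node, b: Node) -> bool:
    """Independent recursive isomorphism oracle (tries both child pairings)."""
    if a.is_leaf or b.is_leaf:
        return a.is_leaf and b.is_leaf
    a1, a2 = a.children
    b1, b2 = b.children
    return (brute_force_isomorphic(a1, b1) and brute_force_isomorphic(a2, b2)) or (
        brute_force_isomorphic(a1, b2) and brute_force_isomorphic(a2, b1)
    )


def test_canonical_equality_matches_brute_force_isomorphism():
    rng = np.random.default_rng(17)
    for _ in range(500):
        n = int(rng.integers(2, 11))
        s1 = shape_of(random_ordered_cladogram(n, rng))
        s2 = shape_of(random_ordered_cladogram(n, rng))
        assert (s1 == s2) == brute_force_isomorphic(s1.root, s2.root)
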