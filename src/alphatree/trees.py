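"""Rooted bifurcating trees: shapes, cladograms, ordered variants.

Four kinds of objects appear in the α-model, connected by forgetful maps:

* :class:`Cladogram` — leaves bijectively labeled by a taxon set;
* :class:`TreeShape` — labels forgotten (isomorphism class);
* :class:`OrderedCladogram` / :class:`OrderedTreeShape` — the variants in
  which each internal node's two children carry a significant order.

Unordered objects are stored in a canonical child order (sorted by
descendant-leaf count, then by a shape encoding, then — for cladograms — by
smallest descendant label), so structural equality coincides with
isomorphism.  The module also provides numerical splits, symmetric branch
points, the root join, preimage counts of the forgetful maps, exhaustive
enumeration for small leaf counts, and Newick I/O (no branch lengths, no
internal labels; shapes use empty leaf names).
"""

from __future__ import annotations

import functools
import itertools
import math
import re
from typing import Iterator, List, Optional, Tuple, Union

__all__ = [
    "Node",
    "TreeShape",
    "Cladogram",
    "OrderedTreeShape",
    "OrderedCladogram",
    "NumericalSplit",
    "SplitMultiset",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "kappa",
    "numerical_splits",
    "symmetric_branch_count",
    "shape_of",
    "forget_order",
    "forget_labels",
    "preimage_count",
    "root_join",
    "enumerate_shapes",
    "enumerate_cladograms",
]


class NewickParseError(ValueError):
    """Malformed or out-of-dialect Newick input."""


class NumericalSplit(Tuple[int, int]):
    """Pair (a, b) of the descendant-leaf counts of an internal node's
    children; (min, max) in unordered trees, child order in ordered ones."""

    __slots__ = ()

    def __new__(cls, a: int, b: int):
        if a < 1 or b < 1:
            raise ValueError(f"numerical split parts must be positive, got ({a}, {b})")
        return super().__new__(cls, (a, b))

    def __repr__(self):
        return f"({self[0]},{self[1]})"


class SplitMultiset:
    """Multiset of numerical splits of a tree, one per internal node.

    Equality is multiset equality (sorted-pair comparison); iteration is in
    sorted order.  For an n-leaf tree the cardinality is n − 1 and the root's
    split sums to n.
    """

    __slots__ = ("_splits",)

    def __init__(self, splits):
        object.__setattr__(self, "_splits", tuple(sorted(NumericalSplit(a, b) for a, b in splits)))

    def __setattr__(self, name, value):
        raise AttributeError("SplitMultiset is immutable")

    def __iter__(self) -> Iterator[NumericalSplit]:
        return iter(self._splits)

    def __len__(self):
        return len(self._splits)

    def __eq__(self, other):
        if isinstance(other, SplitMultiset):
            return self._splits == other._splits
        if isinstance(other, (list, tuple)):
            # multiset comparison; sets are rejected since duplicates collapse
            return self._splits == tuple(sorted(NumericalSplit(a, b) for a, b in other))
        return NotImplemented

    def __hash__(self):
        return hash(self._splits)

    def union(self, other: "SplitMultiset") -> "SplitMultiset":
        return SplitMultiset(tuple(self) + tuple(other))

    def __repr__(self):
        return "{" + ", ".join(map(repr, self._splits)) + "}"


# ---------------------------------------------------------------------------
# Nodes.
# ---------------------------------------------------------------------------


class Node:
    """Immutable node of a rooted bifurcating tree (out-degree 0 or 2).

    ``label`` is None on internal nodes and on the leaves of shapes.  Nodes
    hash by identity, so subtrees can be shared freely and used as cache
    keys; tree-level equality lives on the wrapper classes.
    """

    __slots__ = ("label", "children", "n_leaves", "_shape_key")

    def __init__(self, label: Optional[str] = None, children: Tuple["Node", ...] = ()):
        if len(children) not in (0, 2):
            raise ValueError("a node has exactly 0 or 2 children")
        if children and label is not None:
            raise ValueError("internal nodes are unlabeled")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "children", tuple(children))
        object.__setattr__(self, "n_leaves", 1 if not children else sum(c.n_leaves for c in children))
        object.__setattr__(self, "_shape_key", None)

    def __setattr__(self, name, value):
        raise AttributeError("Node is immutable")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def shape_key(self) -> str:
        """Order- and label-invariant encoding; equal iff subtrees have the
        same shape."""
        k = self._shape_key
        if k is None:
            if self.is_leaf:
                k = "L"
            else:
                # descending inner sort: "L" > "(", so among subtrees with
                # equal leaf counts the more balanced one encodes smaller
                k1, k2 = sorted((c.shape_key() for c in self.children), reverse=True)
                k = f"({k1}{k2})"
            object.__setattr__(self, "_shape_key", k)
        return k

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def min_label(self) -> str:
        labels = [v.label for v in self.walk() if v.label is not None]
        return min(labels, key=_label_sort_key) if labels else ""

    def __repr__(self):
        return f"<Node {_newick_of(self)}>"


def _label_sort_key(lbl: str):
    # digit strings sort numerically ("2" before "10"); others lexically
    return (0, len(lbl), lbl) if lbl.isdigit() else (1, lbl)


def _canonical(node: Node, keep_labels: bool) -> Node:
    """Rebuild with children sorted by (κ, shape encoding, smallest label)."""
    if node.is_leaf:
        return node if keep_labels else (node if node.label is None else Node())
    kids = [_canonical(c, keep_labels) for c in node.children]
    kids.sort(key=lambda c: (c.n_leaves, c.shape_key(), _label_sort_key(c.min_label())))
    return Node(children=tuple(kids))


def _strip_labels(node: Node) -> Node:
    if node.is_leaf:
        return Node() if node.label is not None else node
    return Node(children=tuple(_strip_labels(c) for c in node.children))


_LEAF = Node()


# ---------------------------------------------------------------------------
# Tree wrapper classes.
# ---------------------------------------------------------------------------


class _BaseTree:
    __slots__ = ("root", "_code")
    ordered = False
    labeled = False

    def __init__(self, root: Node):
        object.__setattr__(self, "root", self._normalize(root))
        object.__setattr__(self, "_code", None)

    def __setattr__(self, name, value):
        raise AttributeError(f"{type(self).__name__} is immutable")

    def _normalize(self, root: Node) -> Node:
        raise NotImplementedError

    # -- queries ----------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves

    def leaves(self) -> List[Node]:
        return [v for v in self.root.walk() if v.is_leaf]

    def internal_nodes(self) -> List[Node]:
        return [v for v in self.root.walk() if not v.is_leaf]

    def kappa(self, v: Node) -> int:
        """Number of descendant leaves of ``v`` (κ); v must belong to the tree."""
        if all(v is not u for u in self.root.walk()):
            raise ValueError("node does not belong to this tree")
        return v.n_leaves

    def numerical_splits(self) -> SplitMultiset:
        """One split per internal node; (min, max) in the unordered kinds."""
        out = []
        for v in self.internal_nodes():
            a, b = (c.n_leaves for c in v.children)
            if not self.ordered and a > b:
                a, b = b, a
            out.append((a, b))
        return SplitMultiset(out)

    def ordered_splits(self) -> Tuple[Tuple[int, int], ...]:
        """Splits in child order (meaningful for the ordered kinds)."""
        return tuple((v.children[0].n_leaves, v.children[1].n_leaves) for v in self.internal_nodes())

    def symmetric_branch_count(self) -> int:
        """Number of internal nodes whose two child subtrees have the same
        shape (labels and order ignored)."""
        return sum(
            1
            for v in self.internal_nodes()
            if v.children[0].shape_key() == v.children[1].shape_key()
        )

    def labels(self) -> List[str]:
        return [v.label for v in self.leaves() if v.label is not None]

    # -- serialization / identity ----------------------------------------
    @property
    def newick(self) -> str:
        code = self._code
        if code is None:
            code = _newick_of(self.root) + ";"
            object.__setattr__(self, "_code", code)
        return code

    def __eq__(self, other):
        if type(other) is not type(self):
            return NotImplemented
        return self.newick == other.newick

    def __hash__(self):
        return hash((type(self).__name__, self.newick))

    def __repr__(self):
        return f"{type(self).__name__}({self.newick!r})"


class TreeShape(_BaseTree):
    """Unlabeled, unordered rooted bifurcating tree (isomorphism class)."""

    __slots__ = ()

    def _normalize(self, root):
        return _canonical(root, keep_labels=False)


class Cladogram(_BaseTree):
    """Rooted bifurcating tree with leaves bijectively labeled by a taxon set."""

    __slots__ = ()
    labeled = True

    def _normalize(self, root):
        labels = [v.label for v in root.walk() if v.is_leaf]
        if any(l is None for l in labels):
            raise ValueError("cladogram leaves must all be labeled")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        return _canonical(root, keep_labels=True)

    def shape(self) -> TreeShape:
        return TreeShape(self.root)

    @property
    def label_set(self) -> frozenset:
        return frozenset(self.labels())


class OrderedTreeShape(_BaseTree):
    """Unlabeled tree in which every internal node's child order matters."""

    __slots__ = ()
    ordered = True

    def _normalize(self, root):
        return _strip_labels(root)

    def shape(self) -> TreeShape:
        return TreeShape(self.root)


class OrderedCladogram(_BaseTree):
    """Labeled tree in which every internal node's child order matters."""

    __slots__ = ()
    ordered = True
    labeled = True

    def _normalize(self, root):
        labels = [v.label for v in root.walk() if v.is_leaf]
        if any(l is None for l in labels) or len(set(labels)) != len(labels):
            raise ValueError("ordered cladogram needs distinct labels on all leaves")
        return root

    def shape(self) -> TreeShape:
        return TreeShape(self.root)


AnyTree = Union[TreeShape, Cladogram, OrderedTreeShape, OrderedCladogram]


# ---------------------------------------------------------------------------
# Forgetful maps.
# ---------------------------------------------------------------------------


def shape_of(t: AnyTree) -> TreeShape:
    """Forget labels and order: the tree's shape (π on cladograms)."""
    return TreeShape(t.root)


def forget_order(t: Union[OrderedCladogram, OrderedTreeShape]):
    """π_o / π_{o,*}: drop child orderings (canonicalizing the result)."""
    if isinstance(t, OrderedCladogram):
        return Cladogram(t.root)
    if isinstance(t, OrderedTreeShape):
        return TreeShape(t.root)
    raise TypeError(f"forget_order expects an ordered tree, got {type(t).__name__}")


def forget_labels(t: Union[Cladogram, OrderedCladogram]):
    """π / π_*: drop leaf labels."""
    if isinstance(t, Cladogram):
        return TreeShape(t.root)
    if isinstance(t, OrderedCladogram):
        return OrderedTreeShape(t.root)
    raise TypeError(f"forget_labels expects a labeled tree, got {type(t).__name__}")


_PI_ALIASES = {
    "pi": "pi",
    "labels": "pi",
    "pi_o": "pi_o",
    "orders": "pi_o",
    "pi_os": "pi_os",
    "pi_o*": "pi_os",
    "ordered_shapes": "pi_os",
}


def preimage_count(target: AnyTree, fmap: str) -> int:
    """Number of preimages of ``target`` under a forgetful map.

    * ``"pi"`` — cladograms with a given shape: n!/2^k;
    * ``"pi_o"`` — ordered cladograms over a cladogram: 2^(n−1);
    * ``"pi_os"`` — ordered shapes over a shape: 2^(n−1−k);

    where k is the number of symmetric branch points of the target.
    """
    try:
        fmap = _PI_ALIASES[fmap]
    except KeyError:
        raise ValueError(f"unknown forgetful map {fmap!r}") from None
    n = target.n_leaves
    if fmap == "pi":
        if not isinstance(target, TreeShape):
            raise TypeError("preimages under pi are counted for a TreeShape")
        k = target.symmetric_branch_count()
        return math.factorial(n) // 2**k
    if fmap == "pi_o":
        if not isinstance(target, Cladogram):
            raise TypeError("preimages under pi_o are counted for a Cladogram")
        return 2 ** (n - 1)
    k = target.symmetric_branch_count()
    if not isinstance(target, TreeShape):
        raise TypeError("preimages under pi_os are counted for a TreeShape")
    return 2 ** (n - 1 - k)


# ---------------------------------------------------------------------------
# Root join.
# ---------------------------------------------------------------------------


def root_join(t1: AnyTree, t2: AnyTree) -> AnyTree:
    """Hang t1 and t2 from a new common root (⋆).

    For labeled kinds the label sets must be disjoint.  In ordered kinds t1
    precedes t2 under the new root; unordered kinds canonicalize.
    """
    if type(t1) is not type(t2):
        raise TypeError("root_join requires two trees of the same kind")
    if t1.labeled:
        common = set(t1.labels()) & set(t2.labels())
        if common:
            raise ValueError(f"overlapping label sets: {sorted(common)}")
    return type(t1)(Node(children=(t1.root, t2.root)))


# ---------------------------------------------------------------------------
# Newick I/O.
# ---------------------------------------------------------------------------


def _newick_of(node: Node) -> str:
    if node.is_leaf:
        return node.label or ""
    a, b = node.children
    return f"({_newick_of(a)},{_newick_of(b)})"


def write_newick(t: AnyTree) -> str:
    """Canonical Newick: unordered kinds in canonical child order, shapes
    with empty leaf names, trailing semicolon."""
    return t.newick


_EMPTY_LEAF = re.compile(r"([(,])(?=\s*[,)])")
_PLACEHOLDER = "@@"


def parse_newick(text: str, mode: str = "cladogram") -> AnyTree:
    """Parse a Newick string into a tree of the requested kind.

    ``mode`` is one of ``cladogram``, ``shape``, ``ordered-cladogram``,
    ``ordered-shape``.  Every internal node must be binary.  In the shape
    modes leaf names (empty or not) are discarded; in the cladogram modes all
    leaves must carry distinct labels.  Branch lengths and internal labels
    are out of dialect and rejected.
    """
    import dendropy

    mode = mode.replace("_", "-")
    if mode not in ("cladogram", "shape", "ordered-cladogram", "ordered-shape"):
        raise ValueError(f"unknown parse mode {mode!r}")
    shape_mode = mode.endswith("shape")
    src = text.strip()
    if not src.endswith(";"):
        src += ";"
    if ":" in src:
        raise NewickParseError("branch lengths are not part of this dialect")
    if shape_mode:
        # dendropy silently drops empty-named leaves; give them unique placeholders
        counter = itertools.count()
        src = _EMPTY_LEAF.sub(lambda m: f"{m.group(1)}{_PLACEHOLDER}{next(counter)}", src)
    try:
        dtree = dendropy.Tree.get(
            data=src, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed Newick near {text!r}: {exc}") from exc

    def build(dnode) -> Node:
        kids = dnode.child_nodes()
        if kids:
            if len(kids) != 2:
                raise NewickParseError(
                    f"non-binary node with {len(kids)} children in {text!r}"
                )
            if dnode.taxon is not None:
                raise NewickParseError("internal node labels are not part of this dialect")
            return Node(children=(build(kids[0]), build(kids[1])))
        label = dnode.taxon.label if dnode.taxon is not None else None
        if shape_mode:
            return Node()
        if label is None or label == _PLACEHOLDER:
            raise NewickParseError(f"unlabeled leaf in cladogram mode: {text!r}")
        return Node(label=str(label))

    root = build(dtree.seed_node)
    if root.is_leaf and root.n_leaves == 1 and not shape_mode and root.label is None:
        raise NewickParseError("empty tree")
    cls = {
        "cladogram": Cladogram,
        "shape": TreeShape,
        "ordered-cladogram": OrderedCladogram,
        "ordered-shape": OrderedTreeShape,
    }[mode]
    try:
        return cls(root)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Exhaustive enumeration.
# ---------------------------------------------------------------------------

MAX_SHAPE_LEAVES = 12
MAX_CLADOGRAM_LEAVES = 8


@functools.lru_cache(maxsize=None)
def _shape_roots(n: int) -> Tuple[Node, ...]:
    if n == 1:
        return (_LEAF,)
    out = []
    for a in range(1, n // 2 + 1):
        b = n - a
        if a < b:
            pairs = itertools.product(_shape_roots(a), _shape_roots(b))
        else:
            pairs = itertools.combinations_with_replacement(
                sorted(_shape_roots(a), key=Node.shape_key), 2
            )
        for x, y in pairs:
            if (x.n_leaves, x.shape_key()) > (y.n_leaves, y.shape_key()):
                x, y = y, x
            out.append(Node(children=(x, y)))
    out.sort(key=Node.shape_key)
    return tuple(out)


def enumerate_shapes(n: int) -> List[TreeShape]:
    """All tree shapes with n leaves (Wedderburn–Etherington many),
    duplicate-free, in a deterministic order."""
    if not 1 <= n <= MAX_SHAPE_LEAVES:
        raise ValueError(f"enumerate_shapes supports 1 <= n <= {MAX_SHAPE_LEAVES}, got {n}")
    return [TreeShape(r) for r in _shape_roots(n)]


@functools.lru_cache(maxsize=None)
def _cladogram_roots(labels: Tuple[str, ...]) -> Tuple[Node, ...]:
    if len(labels) == 1:
        return (Node(label=labels[0]),)
    first, rest = labels[0], labels[1:]
    out = []
    for k in range(len(rest) + 1):
        for extra in itertools.combinations(rest, k):
            left = (first,) + extra
            right = tuple(l for l in rest if l not in extra)
            if not right:
                continue
            for x in _cladogram_roots(left):
                for y in _cladogram_roots(right):
                    out.append(Node(children=(x, y)))
    return tuple(out)


def enumerate_cladograms(n: int, labels: Optional[Tuple[str, ...]] = None) -> List[Cladogram]:
    """All cladograms on {1..n} (or on the given labels): (2n−3)!! many,
    duplicate-free, in a deterministic order."""
    if labels is None:
        if not 1 <= n <= MAX_CLADOGRAM_LEAVES:
            raise ValueError(
                f"enumerate_cladograms supports 1 <= n <= {MAX_CLADOGRAM_LEAVES}, got {n}"
            )
        labels = tuple(str(i) for i in range(1, n + 1))
    if len(labels) != n:
        raise ValueError("label tuple length must equal n")
    return [Cladogram(r) for r in _cladogram_roots(tuple(labels))]


# -- module-level convenience wrappers ---------------------------------------


def kappa(t: AnyTree, v: Node) -> int:
    """κ_T(v): number of descendant leaves of node v in tree t."""
    return t.kappa(v)


def numerical_splits(t: AnyTree) -> SplitMultiset:
    return t.numerical_splits()


def symmetric_branch_count(t: AnyTree) -> int:
    return t.symmetric_branch_count()
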