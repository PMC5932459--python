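"""The sequential leaf-addition growth process of the α-model.

A cladogram on {1..n} is built by inserting leaves 2, …, n one at a time.
With ℓ leaves present, the new leaf may attach to any of the ℓ pendant arcs
(weight 1−α each), to any of the ℓ−2 internal arcs, or above the root
(weight α each); the total weight is ℓ·(1−α) + (ℓ−1)·α = ℓ−α, so the step
probabilities are (1−α)/(ℓ−α) and α/(ℓ−α).  Every cladogram arises from
exactly one insertion history, so the history probability P′ is a
probability distribution on cladograms; summing it over the cladograms with
a given shape gives the shape distribution of the model.

This module provides a seeded sampler (:func:`grow_cladogram`,
:func:`sample_from_model`) and an exhaustive enumerator of all histories
(:func:`enumerate_histories`), which serves as the brute-force oracle
against which the closed-form probabilities are checked.

Growing trees are plain nested tuples (a leaf is an int label, an internal
node a pair) for speed; results are converted to :class:`~alphatree.trees`
objects at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .algebra import (
    SYMBOLIC,
    AlphaValue,
    PolynomialAlpha,
    RationalFunctionAlpha,
)
from .trees import Cladogram, Node, TreeShape

__all__ = [
    "GrowthHistory",
    "HistoryDistribution",
    "grow_cladogram",
    "sample_from_model",
    "enumerate_histories",
    "MAX_HISTORY_LEAVES",
]

MAX_HISTORY_LEAVES = 8  # (2n-3)!! histories; 135135 at n = 8

_TupleTree = Union[int, tuple]


def _tuple_to_node(t: _TupleTree) -> Node:
    if isinstance(t, int):
        return Node(label=str(t))
    a, b = t
    return Node(children=(_tuple_to_node(a), _tuple_to_node(b)))


def _positions(tree: _TupleTree) -> List[Tuple[bool, _TupleTree]]:
    """All single-insertion targets, in a fixed deterministic order:
    pendant arcs by leaf label, then internal arcs in preorder, then the
    new-root position.  Each entry is (is_pendant, tree-after-insertion
    builder input) — the new leaf is substituted later via a callable-free
    rebuild, so this returns (is_pendant, path) with path a tuple of 0/1
    child indices to the node the new leaf is joined to."""
    pendant: List[Tuple[int, Tuple[int, ...]]] = []
    internal: List[Tuple[bool, Tuple[int, ...]]] = []

    def rec(node: _TupleTree, path: Tuple[int, ...]):
        if isinstance(node, int):
            pendant.append((node, path))
            return
        if path:  # arc into this internal node exists unless it is the root
            internal.append((False, path))
        rec(node[0], path + (0,))
        rec(node[1], path + (1,))

    rec(tree, ())
    pendant.sort()
    out: List[Tuple[bool, Tuple[int, ...]]] = [(True, p) for _, p in pendant]
    out.extend(internal)
    out.append((False, ()))  # above the root
    return out


def _insert(tree: _TupleTree, path: Tuple[int, ...], leaf: int) -> _TupleTree:
    """Split the arc above the node at ``path`` and hang the new leaf there."""
    if not path:
        return (tree, leaf)
    a, b = tree
    if path[0] == 0:
        return (_insert(a, path[1:], leaf), b)
    return (a, _insert(b, path[1:], leaf))


@dataclass(frozen=True)
class GrowthHistory:
    """One realized insertion history: the choices taken and its probability.

    ``choices`` holds, per step, the (is_pendant, path) pair that was
    selected; ``probability`` is the exact P′ of the resulting cladogram
    (a Fraction for numeric α, a rational function for symbolic α).
    """

    choices: Tuple[Tuple[bool, Tuple[int, ...]], ...]
    tree: Cladogram
    probability: Union[Fraction, RationalFunctionAlpha]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _grow_tuple(n: int, r: Fraction, rng: np.random.Generator):
    """Grow one tuple-tree of n leaves at exact rational α = r; returns
    (tree, choices, probability)."""
    tree: _TupleTree = 1
    prob = Fraction(1)
    choices = []
    for ell in range(1, n):
        new = ell + 1
        if ell == 1:
            tree = (1, 2)
            choices.append((True, ()))
            continue
        w_pend = 1 - r
        w_int = r
        total = ell - r  # = ell*(1-r) + (ell-1)*r
        pos = _positions(tree)
        u = Fraction(float(rng.random())) * total
        acc = Fraction(0)
        chosen = pos[-1]
        for p in pos:
            acc += w_pend if p[0] else w_int
            if u < acc:
                chosen = p
                break
        is_pend, path = chosen
        tree = _insert(tree, path, new)
        prob *= (w_pend if is_pend else w_int) / total
        choices.append(chosen)
    return tree, tuple(choices), prob


def grow_cladogram(n: int, alpha, seed=None) -> Cladogram:
    """Draw one cladogram on {1..n} from the growth process (law P′_{α,n}).

    ``alpha`` may be a Fraction, a float or a string like ``"1/3"``;
    sampling is exact (the uniform variate is compared against exact
    cumulative weights), and deterministic given a seed or Generator.
    """
    av = AlphaValue.from_any(alpha)
    if av.is_symbolic:
        raise ValueError("sampling requires a numeric α")
    tree, _, _ = _grow_tuple(n, av.exact(), _as_rng(seed))
    return Cladogram(_tuple_to_node(tree))


def sample_from_model(n: int, alpha, seed=None, target: str = "cladogram"):
    """Draw from the α-model itself (not the history process).

    ``target="shape"`` returns the shape of a grown cladogram — exactly the
    model's shape law P*.  ``target="cladogram"`` additionally applies a
    uniformly random relabeling, which turns the history law P′ into the
    cladogram law P (the two differ: P spreads each shape's mass equally
    over its n!/2^k labelings, P′ does not).
    """
    if target not in ("cladogram", "shape"):
        raise ValueError(f"unknown target {target!r}")
    rng = _as_rng(seed)
    av = AlphaValue.from_any(alpha)
    if av.is_symbolic:
        raise ValueError("sampling requires a numeric α")
    tree, _, _ = _grow_tuple(n, av.exact(), rng)
    grown = Cladogram(_tuple_to_node(tree))
    if target == "shape":
        return grown.shape()
    labels = [str(i) for i in range(1, n + 1)]
    perm = rng.permutation(n)
    mapping = {labels[i]: labels[perm[i]] for i in range(n)}

    def relabel(node: Node) -> Node:
        if node.is_leaf:
            return Node(label=mapping[node.label])
        return Node(children=tuple(relabel(c) for c in node.children))

    return Cladogram(relabel(grown.root))


# ---------------------------------------------------------------------------
# Exhaustive enumeration of histories (the brute-force oracle).
# ---------------------------------------------------------------------------


@dataclass
class HistoryDistribution:
    """Exact distribution computed by exhausting all insertion histories.

    ``cladogram_mass`` maps each n-leaf cladogram to its history probability
    P′ (each cladogram has exactly one history); ``shape_mass`` sums P′ over
    the cladograms with each shape, which is the model's shape law.  Values
    are Fractions for numeric α and rational functions for symbolic α.
    """

    n: int
    alpha: AlphaValue
    cladogram_mass: Dict[Cladogram, object] = field(default_factory=dict)
    shape_mass: Dict[TreeShape, object] = field(default_factory=dict)

    @property
    def total(self):
        return sum(self.cladogram_mass.values())


def enumerate_histories(n: int, alpha=SYMBOLIC) -> HistoryDistribution:
    """Enumerate all (2n−3)!! insertion histories and their probabilities.

    For symbolic α every history's P′ is returned as an exact rational
    function; the common denominator ∏_{ℓ=2}^{n−1}(ℓ−α) is factored out so
    the sweep only multiplies linear numerator factors.  Supported for
    n ≤ 8 (135135 histories).
    """
    if not 1 <= n <= MAX_HISTORY_LEAVES:
        raise ValueError(f"enumerate_histories supports 1 <= n <= {MAX_HISTORY_LEAVES}, got {n}")
    av = AlphaValue.from_any(alpha)
    dist = HistoryDistribution(n=n, alpha=av)

    if n == 1:
        t = Cladogram(Node(label="1"))
        dist.cladogram_mass[t] = _one(av)
        dist.shape_mass[t.shape()] = _one(av)
        return dist

    symbolic = av.is_symbolic
    if symbolic:
        w_pend = PolynomialAlpha([1, -1])  # 1 - α
        w_int = PolynomialAlpha([0, 1])  # α
        one = PolynomialAlpha([1])
        den = one
        for ell in range(2, n):
            den = den * PolynomialAlpha([ell, -1])
    else:
        r = av.exact()
        w_pend = 1 - r
        w_int = r
        one = Fraction(1)
        den = Fraction(1)
        for ell in range(2, n):
            den *= ell - r

    results: List[Tuple[_TupleTree, object]] = []

    def rec(tree: _TupleTree, ell: int, num):
        if ell == n:
            results.append((tree, num))
            return
        new = ell + 1
        for is_pend, path in _positions(tree):
            w = w_pend if is_pend else w_int
            rec(_insert(tree, path, new), ell + 1, num * w)

    rec((1, 2), 2, one)

    for tree, num in results:
        clad = Cladogram(_tuple_to_node(tree))
        if symbolic:
            val = RationalFunctionAlpha(num, den)
        else:
            val = num / den
        if clad in dist.cladogram_mass:  # unique-construction property
            raise RuntimeError(f"duplicate history for {clad.newick}")
        dist.cladogram_mass[clad] = val

    for clad, val in dist.cladogram_mass.items():
        s = clad.shape()
        if s in dist.shape_mass:
            dist.shape_mass[s] = dist.shape_mass[s] + val
        else:
            dist.shape_mass[s] = val
    return dist


def _one(av: AlphaValue):
    return RationalFunctionAlpha(PolynomialAlpha([1])) if av.is_symbolic else Fraction(1)
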