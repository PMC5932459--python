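"""The four probability distributions of the α-model and their limit laws.

The α-model grows a tree leaf by leaf: a new leaf attaches to a pendant arc
with weight 1−α and to an internal arc or above the root with weight α.  The
resulting distribution on tree shapes is transported to cladograms and to
the ordered variants by dividing equally among preimages of the forgetful
maps.  Closed forms (with Γ_α(n) = ∏_{i<n}(i−α) and the split kernels φ_α,
q_α from :mod:`alphatree.algebra`):

* cladograms:      P(T)  = 2^(n−1) / (n!·Γ_α(n)) · ∏_{(a,b)∈NS(T)} φ_α(a,b)
* shapes:          P*(S) = 2^(n−k−1) / Γ_α(n) · ∏ φ_α(a,b)   (k symmetric
  branch points)
* ordered shapes:  P°*(S) = ∏ q_α(a,b), equivalently P*(S)/2^(n−1−k)
* ordered cladograms: P°(T) = P(T)/2^(n−1)

α = 1/2 reduces to the uniform model (every cladogram has probability
1/(2n−3)!!) and α = 0 to the Yule model.  Ford's published closed form uses
a doubled kernel q̂_α and is wrong on some trees with ≥ 8 leaves; it is
shipped here only as a comparator (:func:`prob_cladogram_ford_published`).

All headline computations are exact; float α is a convenience layer
evaluated from the exact symbolic result.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

from .algebra import (
    SYMBOLIC,
    AlphaValue,
    RationalFunctionAlpha,
    RF_ONE,
    evaluate,
    gamma_alpha,
    phi_alpha,
    q_alpha,
    qhat_alpha,
    render,
)
from .trees import (
    Cladogram,
    OrderedCladogram,
    OrderedTreeShape,
    SplitMultiset,
    TreeShape,
    enumerate_shapes,
    forget_order,
    root_join,
    shape_of,
)

__all__ = [
    "ProbabilityResult",
    "InvariantViolationError",
    "prob_cladogram",
    "prob_shape",
    "prob_ordered_cladogram",
    "prob_ordered_shape",
    "prob_uniform",
    "prob_yule",
    "prob_cladogram_ford_published",
    "markov_factor_cladogram",
    "check_markov_cladogram",
    "check_ordered_markov",
    "demonstrate_no_shape_markov",
    "cladogram_prob_at",
    "shape_prob_at",
    "double_factorial",
]


class InvariantViolationError(AssertionError):
    """Two routes that must agree produced different values."""


@dataclass(frozen=True)
class ProbabilityResult:
    """A probability as an exact function of α, plus its value when α is fixed.

    ``numeric`` is an exact Fraction for rational α, a float for float α and
    ``None`` for symbolic α; it always equals ``evaluate(symbolic, alpha)``.
    """

    symbolic: RationalFunctionAlpha
    alpha: AlphaValue
    numeric: Optional[Union[Fraction, float]]

    @staticmethod
    def from_symbolic(f: RationalFunctionAlpha, alpha) -> "ProbabilityResult":
        av = AlphaValue.from_any(alpha)
        num = None if av.is_symbolic else evaluate(f, av)
        return ProbabilityResult(f, av, num)

    def __str__(self):
        if self.numeric is None:
            return render(self.symbolic)
        return str(self.numeric)


def double_factorial(m: int) -> int:
    """(m)!! for odd m ≥ -1; (2n−3)!! counts the cladograms on n leaves."""
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


# ---------------------------------------------------------------------------
# Symbolic closed forms.
# ---------------------------------------------------------------------------


def _phi_product(splits) -> RationalFunctionAlpha:
    out = RF_ONE
    for a, b in splits:
        out = out * phi_alpha(a, b)
    return out


def prob_cladogram(T: Cladogram, alpha=SYMBOLIC) -> ProbabilityResult:
    """Probability of a cladogram: 2^(n−1)/(n!·Γ_α(n)) · ∏ φ_α over NS(T).

    Depends on T only through its multiset of numerical splits.  n = 1
    returns 1.
    """
    n = T.n_leaves
    if n == 1:
        return ProbabilityResult.from_symbolic(RF_ONE, alpha)
    f = (
        _phi_product(T.numerical_splits())
        / gamma_alpha(n)
        * Fraction(2 ** (n - 1), math.factorial(n))
    )
    return ProbabilityResult.from_symbolic(f, alpha)


def prob_shape(S: TreeShape, alpha=SYMBOLIC) -> ProbabilityResult:
    """Probability of a tree shape: 2^(n−k−1)/Γ_α(n) · ∏ φ_α over NS(S),
    with k the number of symmetric branch points."""
    n = S.n_leaves
    if n == 1:
        return ProbabilityResult.from_symbolic(RF_ONE, alpha)
    k = S.symmetric_branch_count()
    f = _phi_product(S.numerical_splits()) / gamma_alpha(n) * Fraction(2 ** (n - k - 1))
    return ProbabilityResult.from_symbolic(f, alpha)


def prob_ordered_cladogram(T_o: OrderedCladogram, alpha=SYMBOLIC) -> ProbabilityResult:
    """Probability of an ordered cladogram: P(forget_order(T_o)) / 2^(n−1)."""
    n = T_o.n_leaves
    base = prob_cladogram(forget_order(T_o))
    f = base.symbolic * Fraction(1, 2 ** (n - 1))
    return ProbabilityResult.from_symbolic(f, alpha)


def prob_ordered_shape(S_o: OrderedTreeShape, alpha=SYMBOLIC) -> ProbabilityResult:
    """Probability of an ordered tree shape, by two routes that must agree.

    Route 1 (transport): P*(shape)/2^(n−1−k).  Route 2 (product formula):
    ∏ q_α(a,b) over the splits.  A mismatch raises
    :class:`InvariantViolationError` — it would mean a real defect, since
    their equality is a theorem.
    """
    n = S_o.n_leaves
    if n == 1:
        return ProbabilityResult.from_symbolic(RF_ONE, alpha)
    shape = S_o.shape()
    k = shape.symmetric_branch_count()
    via_transport = prob_shape(shape).symbolic * Fraction(1, 2 ** (n - 1 - k))
    via_product = RF_ONE
    for a, b in S_o.ordered_splits():
        via_product = via_product * q_alpha(a, b)
    if via_transport != via_product:
        raise InvariantViolationError(
            f"ordered-shape routes disagree on {S_o.newick}: "
            f"{render(via_transport)} vs {render(via_product)}"
        )
    return ProbabilityResult.from_symbolic(via_product, alpha)


def prob_uniform(n: int) -> Fraction:
    """Uniform (PDA) probability of any n-leaf cladogram: 1/(2n−3)!!."""
    if n < 2:
        raise ValueError("uniform law needs n >= 2")
    return Fraction(1, double_factorial(2 * n - 3))


def prob_yule(T: Cladogram) -> Fraction:
    """Yule probability 2^(n−1)/n! · ∏_v 1/(κ(v)−1) over internal nodes."""
    n = T.n_leaves
    if n == 1:
        return Fraction(1)
    denom = 1
    for v in T.internal_nodes():
        denom *= v.n_leaves - 1
    return Fraction(2 ** (n - 1), math.factorial(n) * denom)


def prob_cladogram_ford_published(T: Cladogram, alpha=SYMBOLIC) -> ProbabilityResult:
    """Ford's published cladogram formula 2^k/n! · ∏ q̂_α over NS(T).

    COMPARATOR ONLY — this is the erroneous closed form.  It agrees with
    :func:`prob_cladogram` exactly when every internal node with equal child
    leaf counts has shape-isomorphic child subtrees, and is off by powers of
    2 otherwise (first failure: one 8-leaf shape, where it returns half the
    correct value).
    """
    n = T.n_leaves
    if n == 1:
        return ProbabilityResult.from_symbolic(RF_ONE, alpha)
    k = T.symmetric_branch_count()
    f = RationalFunctionAlpha(Fraction(2**k, math.factorial(n)))
    for a, b in T.numerical_splits():
        f = f * qhat_alpha(a, b)
    return ProbabilityResult.from_symbolic(f, alpha)


# ---------------------------------------------------------------------------
# Markov branching recurrences.
# ---------------------------------------------------------------------------


def markov_factor_cladogram(m: int, n: int) -> RationalFunctionAlpha:
    """The cladogram recurrence factor 2·q_α(m, n−m)/C(n, m), so that
    P(T_m ⋆ T_{n−m}) = factor · P(T_m) · P(T_{n−m})."""
    if not 0 < m < n:
        raise ValueError(f"need 0 < m < n, got m={m}, n={n}")
    return 2 * q_alpha(m, n - m) * Fraction(1, math.comb(n, m))


def check_markov_cladogram(T_m: Cladogram, T_rest: Cladogram, alpha=SYMBOLIC) -> bool:
    """Verify P(T_m ⋆ T_rest) = [2 q_α(m, n−m)/C(n,m)]·P(T_m)·P(T_rest)."""
    m, n = T_m.n_leaves, T_m.n_leaves + T_rest.n_leaves
    joined = root_join(T_m, T_rest)
    lhs = prob_cladogram(joined).symbolic
    rhs = markov_factor_cladogram(m, n) * prob_cladogram(T_m).symbolic * prob_cladogram(T_rest).symbolic
    av = AlphaValue.from_any(alpha)
    if av.is_symbolic:
        return lhs == rhs
    return evaluate(lhs, av) == evaluate(rhs, av)


def check_ordered_markov(S_m: OrderedTreeShape, S_rest: OrderedTreeShape, alpha=SYMBOLIC) -> bool:
    """Verify the ordered-shape recurrence
    P°*(S_m ⋆ S_rest) = q_α(m, n−m)·P°*(S_m)·P°*(S_rest)."""
    m, nm = S_m.n_leaves, S_rest.n_leaves
    joined = root_join(S_m, S_rest)
    lhs = prob_ordered_shape(joined).symbolic
    rhs = q_alpha(m, nm) * prob_ordered_shape(S_m).symbolic * prob_ordered_shape(S_rest).symbolic
    av = AlphaValue.from_any(alpha)
    if av.is_symbolic:
        return lhs == rhs
    return evaluate(lhs, av) == evaluate(rhs, av)


@dataclass(frozen=True)
class NoShapeMarkovReport:
    """Witness that unordered shape probabilities admit no Markov branching
    recurrence: the two implied factors differ by an exact factor of 2."""

    shape_a: TreeShape
    shape_b: TreeShape
    prob_a: RationalFunctionAlpha
    prob_b: RationalFunctionAlpha
    prob_aa: RationalFunctionAlpha  # P*(A ⋆ A)
    prob_ab: RationalFunctionAlpha  # P*(A ⋆ B)
    factor_same: RationalFunctionAlpha  # P*(A⋆A)/P*(A)² = q_α(m,m)
    factor_mixed: RationalFunctionAlpha  # P*(A⋆B)/(P*(A)·P*(B)) = 2·q_α(m,m)

    def __str__(self):
        m = self.shape_a.n_leaves
        return (
            f"shapes A = {self.shape_a.newick}  B = {self.shape_b.newick}\n"
            f"P*(A) = {render(self.prob_a)}\n"
            f"P*(B) = {render(self.prob_b)}\n"
            f"P*(A*A) = {render(self.prob_aa)}\n"
            f"P*(A*B) = {render(self.prob_ab)}\n"
            f"P*(A*A)/P*(A)^2   = {render(self.factor_same)} = q_a({m},{m})\n"
            f"P*(A*B)/(P*(A)P*(B)) = {render(self.factor_mixed)} = 2*q_a({m},{m})\n"
            "No single Q(m,m) satisfies both, so no Markov branching "
            "recurrence exists for unordered tree shapes."
        )


def demonstrate_no_shape_markov(m: int = 6) -> NoShapeMarkovReport:
    """Exhibit two distinct m-leaf shapes with equal symmetric-branch count
    whose root joins force incompatible recurrence factors (q vs 2q).

    The smallest m with two distinct equal-k shapes is 6 (m = 4 and 5 have
    one shape per k value); smaller m raises."""
    by_k = {}
    pair = None
    for s in enumerate_shapes(m):
        k = s.symmetric_branch_count()
        if k in by_k:
            pair = (by_k[k], s)
            break
        by_k[k] = s
    if pair is None:
        raise ValueError(
            f"no two distinct {m}-leaf shapes share a symmetric-branch count; "
            "the smallest m admitting the counterexample is 6"
        )
    A, B = pair
    pa = prob_shape(A).symbolic
    pb = prob_shape(B).symbolic
    paa = prob_shape(root_join(A, A)).symbolic
    pab = prob_shape(root_join(A, B)).symbolic
    return NoShapeMarkovReport(
        shape_a=A,
        shape_b=B,
        prob_a=pa,
        prob_b=pb,
        prob_aa=paa,
        prob_ab=pab,
        factor_same=paa / (pa * pa),
        factor_mixed=pab / (pa * pb),
    )


# ---------------------------------------------------------------------------
# Fast exact paths for exhaustive sweeps (memoized on the split multiset).
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def _phi_at(a: int, b: int, r: Fraction) -> Fraction:
    c2 = math.comb(a + b - 2, a - 1)
    return Fraction(math.comb(a + b, a)) * r / 2 + (1 - 2 * r) * c2


@functools.lru_cache(maxsize=None)
def _gamma_at(n: int, r: Fraction) -> Fraction:
    out = Fraction(1)
    for i in range(1, n):
        out *= i - r
    return out


@functools.lru_cache(maxsize=None)
def _split_product_at(splits: tuple, r: Fraction) -> Fraction:
    out = Fraction(1)
    for a, b in splits:
        out *= _phi_at(a, b, r)
    return out


def cladogram_prob_at(splits: SplitMultiset, n: int, r: Fraction) -> Fraction:
    """Exact cladogram probability at rational α = r from a split multiset.

    Equivalent to ``prob_cladogram(T, r).numeric`` but memoized on the split
    multiset, which is what makes exhaustive sweeps over all 135135 trees of
    𝒯₈ cheap.  α = 1 must go through the symbolic route (Γ₁(n) = 0 before
    cancellation).
    """
    r = Fraction(r)
    if r == 1:
        raise ValueError("α = 1 requires the symbolic route (removable singularity)")
    return (
        Fraction(2 ** (n - 1), math.factorial(n))
        * _split_product_at(tuple(splits), r)
        / _gamma_at(n, r)
    )


def shape_prob_at(splits: SplitMultiset, n: int, k: int, r: Fraction) -> Fraction:
    """Exact shape probability at rational α = r (k symmetric branch points)."""
    r = Fraction(r)
    if r == 1:
        raise ValueError("α = 1 requires the symbolic route (removable singularity)")
    return Fraction(2 ** (n - k - 1)) * _split_product_at(tuple(splits), r) / _gamma_at(n, r)
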