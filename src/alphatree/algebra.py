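"""Exact univariate rational-function arithmetic in the model parameter α.

Every probability in the α-model is a ratio of polynomials in α with rational
coefficients.  This module provides the two carrier types
(:class:`PolynomialAlpha`, :class:`RationalFunctionAlpha`), the model kernels
Γ_α, φ_α and q_α, and Ford's published doubling variant q̂_α, which is kept
only as a comparator for reproducing the factor-of-2 error in the published
cladogram formula.

All arithmetic is exact: coefficients are :class:`fractions.Fraction` over
arbitrary-precision integers, and rational functions are kept in a canonical
reduced form so that equality of probabilities is structural equality.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Union

__all__ = [
    "PolynomialAlpha",
    "RationalFunctionAlpha",
    "AlphaValue",
    "SYMBOLIC",
    "PoleError",
    "gamma_alpha",
    "phi_alpha",
    "q_alpha",
    "qhat_alpha",
    "evaluate",
    "render",
    "parse",
]


class PoleError(ZeroDivisionError):
    """Raised when a rational function is evaluated at a true pole."""


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    raise TypeError(f"expected an exact rational coefficient, got {type(x).__name__}")


class PolynomialAlpha:
    """Dense univariate polynomial in α with exact rational coefficients.

    Coefficients are stored lowest power first; trailing zeros are stripped so
    the representation (and hence ``==`` and ``hash``) is canonical.  The zero
    polynomial is the empty coefficient tuple.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: Iterable[Union[int, Fraction]] = ()):
        cs = [_as_fraction(c) for c in coeffs]
        while cs and cs[-1] == 0:
            cs.pop()
        object.__setattr__(self, "coeffs", tuple(cs))

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("PolynomialAlpha is immutable")

    # -- basic queries ----------------------------------------------------
    @property
    def degree(self) -> int:
        """Degree; -1 for the zero polynomial."""
        return len(self.coeffs) - 1

    def is_zero(self) -> bool:
        return not self.coeffs

    def leading(self) -> Fraction:
        if not self.coeffs:
            raise ValueError("zero polynomial has no leading coefficient")
        return self.coeffs[-1]

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "PolynomialAlpha") -> "PolynomialAlpha":
        other = _coerce_poly(other)
        a, b = self.coeffs, other.coeffs
        if len(a) < len(b):
            a, b = b, a
        out = list(a)
        for i, c in enumerate(b):
            out[i] += c
        return PolynomialAlpha(out)

    def __neg__(self) -> "PolynomialAlpha":
        return PolynomialAlpha([-c for c in self.coeffs])

    def __sub__(self, other):
        return self + (-_coerce_poly(other))

    def __mul__(self, other) -> "PolynomialAlpha":
        other = _coerce_poly(other)
        a, b = self.coeffs, other.coeffs
        if not a or not b:
            return PolynomialAlpha()
        out = [Fraction(0)] * (len(a) + len(b) - 1)
        for i, ca in enumerate(a):
            if ca:
                for j, cb in enumerate(b):
                    out[i + j] += ca * cb
        return PolynomialAlpha(out)

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return _coerce_poly(other) - self

    def scale(self, c: Union[int, Fraction]) -> "PolynomialAlpha":
        c = _as_fraction(c)
        return PolynomialAlpha([c * x for x in self.coeffs])

    def divmod(self, other: "PolynomialAlpha"):
        """Euclidean division: returns (q, r) with self = q*other + r."""
        if other.is_zero():
            raise ZeroDivisionError("polynomial division by zero")
        r = list(self.coeffs)
        d = other.coeffs
        dd = len(d) - 1
        lead = d[-1]
        if len(r) - 1 < dd:
            return PolynomialAlpha(), self
        q = [Fraction(0)] * (len(r) - dd)
        for i in range(len(r) - 1, dd - 1, -1):
            if r[i]:
                f = r[i] / lead
                q[i - dd] = f
                for j in range(dd + 1):
                    r[i - dd + j] -= f * d[j]
        return PolynomialAlpha(q), PolynomialAlpha(r)

    def gcd(self, other: "PolynomialAlpha") -> "PolynomialAlpha":
        """Monic GCD via the Euclidean algorithm over ℚ."""
        a, b = self, other
        while not b.is_zero():
            a, b = b, a.divmod(b)[1]
        if a.is_zero():
            return a
        return a.scale(1 / a.leading())

    def __call__(self, x):
        """Evaluate by Horner's rule; exact for Fraction inputs."""
        acc = Fraction(0) if isinstance(x, (int, Fraction)) else 0.0
        for c in reversed(self.coeffs):
            acc = acc * x + c
        return acc

    # -- comparison / hashing --------------------------------------------
    def __eq__(self, other):
        if isinstance(other, (int, Fraction)):
            other = _coerce_poly(other)
        if not isinstance(other, PolynomialAlpha):
            return NotImplemented
        return self.coeffs == other.coeffs

    def __hash__(self):
        return hash(("PolynomialAlpha", self.coeffs))

    def __repr__(self):
        return f"PolynomialAlpha({list(self.coeffs)!r})"


def _coerce_poly(x) -> PolynomialAlpha:
    if isinstance(x, PolynomialAlpha):
        return x
    if isinstance(x, (int, Fraction)):
        return PolynomialAlpha([x])
    raise TypeError(f"cannot coerce {type(x).__name__} to PolynomialAlpha")


ALPHA = PolynomialAlpha([0, 1])
ONE_POLY = PolynomialAlpha([1])


def _primitive(p: PolynomialAlpha):
    """Write p = c * P with P an integer polynomial of content 1 and positive
    leading coefficient; returns (c, P)."""
    if p.is_zero():
        return Fraction(0), p
    den_lcm = 1
    for c in p.coeffs:
        den_lcm = den_lcm * c.denominator // math.gcd(den_lcm, c.denominator)
    ints = [int(c * den_lcm) for c in p.coeffs]
    g = 0
    for v in ints:
        g = math.gcd(g, v)
    if ints[-1] < 0:
        g = -g
    return Fraction(g, den_lcm), PolynomialAlpha([Fraction(v, g) for v in ints])


class RationalFunctionAlpha:
    """Ratio of two :class:`PolynomialAlpha`, canonically reduced.

    Canonical form: numerator and denominator share no nonconstant factor,
    the denominator has coprime integer coefficients with positive leading
    coefficient, and the whole rational scale is carried by the numerator.
    Under this normalization equality of values is equality of
    representations, which is what lets probability identities be asserted
    bit-exactly.
    """

    __slots__ = ("num", "den")

    def __init__(self, num, den=ONE_POLY):
        num = _coerce_poly(num)
        den = _coerce_poly(den)
        if den.is_zero():
            raise ZeroDivisionError("rational function with zero denominator")
        if num.is_zero():
            object.__setattr__(self, "num", PolynomialAlpha())
            object.__setattr__(self, "den", ONE_POLY)
            return
        g = num.gcd(den)
        if g.degree > 0:
            num = num.divmod(g)[0]
            den = den.divmod(g)[0]
        c, dprim = _primitive(den)
        num = num.scale(1 / c)
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", dprim)

    def __setattr__(self, name, value):
        raise AttributeError("RationalFunctionAlpha is immutable")

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _coerce_rf(other)
        return RationalFunctionAlpha(
            self.num * other.den + other.num * self.den, self.den * other.den
        )

    def __neg__(self):
        return RationalFunctionAlpha(-self.num, self.den)

    def __sub__(self, other):
        return self + (-_coerce_rf(other))

    def __rsub__(self, other):
        return _coerce_rf(other) - self

    def __mul__(self, other):
        other = _coerce_rf(other)
        return RationalFunctionAlpha(self.num * other.num, self.den * other.den)

    def __truediv__(self, other):
        other = _coerce_rf(other)
        if other.num.is_zero():
            raise ZeroDivisionError("division by the zero rational function")
        return RationalFunctionAlpha(self.num * other.den, self.den * other.num)

    def __rtruediv__(self, other):
        return _coerce_rf(other) / self

    __radd__ = __add__
    __rmul__ = __mul__

    def is_zero(self) -> bool:
        return self.num.is_zero()

    def is_constant(self) -> bool:
        return self.num.degree <= 0 and self.den.degree == 0

    def __eq__(self, other):
        if isinstance(other, (int, Fraction, PolynomialAlpha)):
            other = _coerce_rf(other)
        if not isinstance(other, RationalFunctionAlpha):
            return NotImplemented
        return self.num == other.num and self.den == other.den

    def __hash__(self):
        return hash(("RationalFunctionAlpha", self.num.coeffs, self.den.coeffs))

    def __call__(self, alpha):
        return evaluate(self, alpha)

    def __repr__(self):
        return f"RationalFunctionAlpha({render(self)!r})"

    def __str__(self):
        return render(self)


def _coerce_rf(x) -> RationalFunctionAlpha:
    if isinstance(x, RationalFunctionAlpha):
        return x
    if isinstance(x, (int, Fraction, PolynomialAlpha)):
        return RationalFunctionAlpha(_coerce_poly(x))
    raise TypeError(f"cannot coerce {type(x).__name__} to RationalFunctionAlpha")


RF_ONE = RationalFunctionAlpha(ONE_POLY)


# ---------------------------------------------------------------------------
# The parameter α: symbolic, exact rational, or float.
# ---------------------------------------------------------------------------


class _Symbolic:
    """Sentinel for a symbolic (unevaluated) α."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "SYMBOLIC"


SYMBOLIC = _Symbolic()


@dataclass(frozen=True)
class AlphaValue:
    """The model parameter α ∈ [0, 1]: symbolic, exact rational, or float.

    Construct with :meth:`from_any`, which accepts ``SYMBOLIC`` / ``None`` /
    ``"sym"``, a :class:`~fractions.Fraction` or int, a string like ``"1/3"``
    or ``"0.25"``, or a float.  String rationals take precedence over float
    parsing so CLI input stays exact whenever it can.
    """

    kind: str  # "symbolic" | "rational" | "float"
    value: object = None

    @staticmethod
    def from_any(x) -> "AlphaValue":
        if isinstance(x, AlphaValue):
            return x
        if x is None or x is SYMBOLIC or (isinstance(x, str) and x.lower() in ("sym", "symbolic", "a", "alpha")):
            return AlphaValue("symbolic")
        if isinstance(x, str):
            try:
                v = Fraction(x)
            except ValueError as exc:
                raise ValueError(f"cannot parse α from {x!r}") from exc
            return AlphaValue.from_any(v)
        if isinstance(x, (int, Fraction)):
            v = Fraction(x)
            if not 0 <= v <= 1:
                raise ValueError(f"α must lie in [0, 1], got {v}")
            return AlphaValue("rational", v)
        if isinstance(x, float):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"α must lie in [0, 1], got {x}")
            return AlphaValue("float", x)
        raise TypeError(f"cannot interpret {type(x).__name__} as α")

    @property
    def is_symbolic(self) -> bool:
        return self.kind == "symbolic"

    def exact(self) -> Fraction:
        """The parameter as an exact rational (floats converted exactly)."""
        if self.kind == "rational":
            return self.value
        if self.kind == "float":
            return Fraction(self.value)
        raise ValueError("symbolic α has no numeric value")

    def __str__(self):
        return "α" if self.is_symbolic else str(self.value)


# ---------------------------------------------------------------------------
# Model kernels.
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def gamma_alpha(n: int) -> RationalFunctionAlpha:
    """Γ_α(n) = ∏_{i=1}^{n-1} (i − α), the model's factorial analogue.

    Γ_α(1) = 1 and Γ_α(n) = (n−1−α)·Γ_α(n−1); a polynomial of degree n−1.
    At α=0 this is (n−1)!.
    """
    if n < 1:
        raise ValueError(f"gamma_alpha requires n >= 1, got {n}")
    if n == 1:
        return RF_ONE
    prev = gamma_alpha(n - 1)
    return RationalFunctionAlpha(prev.num * PolynomialAlpha([n - 1, -1]), prev.den)


@functools.lru_cache(maxsize=None)
def phi_alpha(a: int, b: int) -> RationalFunctionAlpha:
    """The split weight φ_α(a,b) = (α/2)·C(a+b,a) + (1−2α)·C(a+b−2,a−1).

    Symmetric in (a, b) and linear in α.  The product of φ_α over the
    numerical splits of a tree, normalized by Γ_α, gives the tree's
    probability.
    """
    if a < 1 or b < 1:
        raise ValueError(f"phi_alpha requires positive arguments, got ({a}, {b})")
    c1 = Fraction(math.comb(a + b, a), 2)
    c2 = Fraction(math.comb(a + b - 2, a - 1))
    # constant term c2, α-coefficient c1 - 2*c2
    return RationalFunctionAlpha(PolynomialAlpha([c2, c1 - 2 * c2]))


@functools.lru_cache(maxsize=None)
def q_alpha(a: int, b: int) -> RationalFunctionAlpha:
    """q_α(a,b) = Γ_α(a)·Γ_α(b)/Γ_α(a+b) · φ_α(a,b), reduced and symmetric."""
    if a < 1 or b < 1:
        raise ValueError(f"q_alpha requires positive arguments, got ({a}, {b})")
    return gamma_alpha(a) * gamma_alpha(b) / gamma_alpha(a + b) * phi_alpha(a, b)


def qhat_alpha(a: int, b: int) -> RationalFunctionAlpha:
    """Ford's published q̂_α: 2·q_α(a,b) for a ≠ b, q_α(a,b) for a = b.

    Comparator only — the doubling is the source of the factor-of-2 error in
    the published cladogram formula and is never used by the corrected
    probabilities.
    """
    q = q_alpha(a, b)
    return q if a == b else 2 * q


# ---------------------------------------------------------------------------
# Evaluation.
# ---------------------------------------------------------------------------


def evaluate(f: RationalFunctionAlpha, alpha):
    """Evaluate ``f`` at α.

    Symbolic α returns ``f`` unchanged.  Rational α returns an exact
    Fraction; float α returns a float.  Since ``f`` is stored reduced,
    removable singularities (such as α = 1, where Γ_α(2) = 0 before
    cancellation) evaluate correctly; a remaining zero of the denominator is
    a true pole and raises :class:`PoleError`.
    """
    av = AlphaValue.from_any(alpha)
    if av.is_symbolic:
        return f
    r = av.exact()
    den = f.den(r)
    if den == 0:
        raise PoleError(f"true pole at α = {r}: denominator factor vanishes at {r}")
    val = f.num(r) / den
    return float(val) if av.kind == "float" else val


# ---------------------------------------------------------------------------
# Canonical ASCII rendering and parsing ("a" denotes α).
# ---------------------------------------------------------------------------


def _rational_roots(p: PolynomialAlpha):
    """Split p into rational-root linear factors and a rootless remainder.

    Returns (roots, remainder) with roots sorted ascending (multiplicity as
    repetition) and p = leading-structure · ∏(α − r) · remainder up to a
    constant handled by the caller.
    """
    roots = []
    while p.degree >= 1:
        _, prim = _primitive(p)
        a0 = prim.coeffs[0]
        an = prim.coeffs[-1]
        found = None
        if a0 == 0:
            found = Fraction(0)
        else:
            p_divs = [d for d in range(1, abs(int(a0)) + 1) if int(a0) % d == 0]
            q_divs = [d for d in range(1, abs(int(an)) + 1) if int(an) % d == 0]
            for pd in p_divs:
                for qd in q_divs:
                    for cand in (Fraction(pd, qd), Fraction(-pd, qd)):
                        if p(cand) == 0:
                            found = cand
                            break
                    if found is not None:
                        break
                if found is not None:
                    break
        if found is None:
            break
        p = p.divmod(PolynomialAlpha([-found, 1]))[0]
        roots.append(found)
    roots.sort()
    return roots, p


def _frac_str(f: Fraction) -> str:
    return str(f.numerator) if f.denominator == 1 else f"{f.numerator}/{f.denominator}"


def _render_poly_factored(p: PolynomialAlpha):
    """Render p as (constant, [factor strings]) with factors by root ascending.

    A root r > 0 renders as ``(r-a)`` (sign absorbed into the constant),
    r = 0 as ``a``, r < 0 as ``(a+|r|)``; a rootless remainder of degree ≥ 2
    renders expanded in ascending powers.
    """
    roots, rem = _rational_roots(p)
    const = rem.leading() if rem.degree == 0 else Fraction(1)
    factors = []
    for r in roots:
        if r > 0:
            const = -const
            factors.append(f"({_frac_str(r)}-a)")
        elif r == 0:
            factors.append("a")
        else:
            factors.append(f"(a+{_frac_str(-r)})")
    if rem.degree >= 2:
        c, prim = _primitive(rem)
        const *= c
        terms = []
        for i, coef in enumerate(prim.coeffs):
            if coef == 0:
                continue
            if i == 0:
                terms.append(_frac_str(coef))
            else:
                mono = "a" if i == 1 else f"a^{i}"
                terms.append(mono if coef == 1 else f"{_frac_str(coef)}*{mono}")
        factors.append("(" + "+".join(terms).replace("+-", "-") + ")")
    # roots with multiplicity: collapse repeats into powers
    collapsed = []
    i = 0
    while i < len(factors):
        j = i
        while j < len(factors) and factors[j] == factors[i]:
            j += 1
        collapsed.append(factors[i] if j - i == 1 else f"{factors[i]}^{j - i}")
        i = j
    return const, collapsed


def render(f: RationalFunctionAlpha) -> str:
    """Canonical ASCII form, e.g. ``2*(1-a)/(4-a)``.

    Linear factors are ordered by root, ascending; the constant in front is
    an exact rational.  Stable across runs, so suitable for golden files.
    """
    if f.num.is_zero():
        return "0"
    cn, nf = _render_poly_factored(f.num)
    cd, df = _render_poly_factored(f.den)
    const = cn / cd
    if const == 1 and nf:
        num_parts = list(nf)
    elif const == -1 and nf:
        num_parts = ["-" + nf[0]] + list(nf[1:])
    else:
        num_parts = [_frac_str(const)] + list(nf)
    num_s = "*".join(num_parts)
    if not df:
        return num_s
    den_s = "*".join(df)
    if len(df) > 1:
        den_s = f"({den_s})"
    return f"{num_s}/{den_s}"


def parse(text: str) -> RationalFunctionAlpha:
    """Parse the canonical ASCII form (or any sympy-readable expression in
    ``a``) back into a :class:`RationalFunctionAlpha`."""
    import sympy

    a = sympy.Symbol("a")
    expr = sympy.sympify(text, locals={"a": a}, rational=True)
    num, den = sympy.together(expr).as_numer_denom()
    return RationalFunctionAlpha(_poly_from_sympy(num, a), _poly_from_sympy(den, a))


def _poly_from_sympy(expr, a) -> PolynomialAlpha:
    import sympy

    poly = sympy.Poly(expr, a, domain="QQ")
    coeffs = [Fraction(c.p, c.q) for c in reversed(poly.all_coeffs())]
    return PolynomialAlpha(coeffs)


def to_sympy(f: RationalFunctionAlpha):
    """Convert to a sympy expression in the symbol ``a`` (cross-check hook)."""
    import sympy

    a = sympy.Symbol("a")
    num = sum(sympy.Rational(c.numerator, c.denominator) * a**i for i, c in enumerate(f.num.coeffs))
    den = sum(sympy.Rational(c.numerator, c.denominator) * a**i for i, c in enumerate(f.den.coeffs))
    return sympy.simplify(num / den)
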