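# Methods

## The model

The α-model is a Markovian leaf-addition process on rooted bifurcating
trees. Starting from the unique one- and two-leaf trees, the tree with
ℓ + 1 leaves is obtained from the tree with ℓ leaves by attaching the new
leaf (labeled ℓ + 1) to an arc: each of the ℓ pendant arcs carries weight
1 − α, and each of the ℓ − 2 internal arcs as well as the position above
the root carries weight α. The total weight is ℓ(1 − α) + (ℓ − 1)α = ℓ − α,
so the step probabilities are (1 − α)/(ℓ − α) and α/(ℓ − α). Published
descriptions of the process state the weights but not the complete census
of insertion positions; that the "new root" position is available at every
step is forced by the requirement that step probabilities sum to one, and
the package enforces this accounting by testing that the total mass of all
insertion histories is exactly 1, symbolically in α.

Every cladogram arises from exactly one insertion history, so the history
law P′ is a distribution on cladograms. The model's shape law P\* sums P′
over the labelings of a shape; it is then transported to cladograms,
ordered shapes and ordered cladograms by dividing equally among the
preimages of the forgetful maps (n!/2^k labelings of a shape with k
symmetric branch points; 2^(n−1) orderings of a cladogram; 2^(n−1−k)
ordered shapes over a shape).

Closed forms, with Γ_α(n) = ∏_{i=1}^{n−1}(i − α) and
φ_α(a,b) = (α/2)·C(a+b,a) + (1 − 2α)·C(a+b−2,a−1):

* P(T) = 2^(n−1)/(n!·Γ_α(n)) · ∏_{(a,b)∈NS(T)} φ_α(a,b) for cladograms,
* P\*(S) = 2^(n−k−1)/Γ_α(n) · ∏ φ_α(a,b) for shapes,
* P°\*(S) = ∏ q_α(a,b) for ordered shapes, with
  q_α(a,b) = Γ_α(a)Γ_α(b)/Γ_α(a+b)·φ_α(a,b).

The definition of φ_α is typeset ambiguously in the published account;
the reading above is pinned down by four independent laws that the test
suite enforces: the two-leaf cladogram has probability 1; the closed form
reproduces the printed worked example on the 8-leaf counterexample tree;
α = 1/2 yields the uniform law 1/(2n−3)!! on every cladogram with n ≤ 8;
and α = 0 yields the Yule law 2^(n−1)/n!·∏ 1/(κ(v)−1). Any alternative
reading must re-pass all four.

One figure sometimes quoted alongside this material is a typo: the
Yule-point value of the 8-leaf counterexample tree appears as 1/19845 in
the published worked example, but both the
closed form at α = 0 and the Yule product give 1/39690 (half of it), and
the exhaustive growth oracle confirms 1/39690. The package follows the
formulas, not the printed number.

## The published comparator

Ford's published closed form replaces q_α by q̂_α (doubled off the
diagonal) and the prefactor 2^(n−1) by 2^k. The two expressions agree
exactly when every internal node whose children have equal leaf counts has
shape-isomorphic child subtrees; each internal node violating this
("defect" node: equal κ, non-isomorphic shapes) costs the published value
a factor of 2. The smallest tree with a defect node joins the balanced and
the caterpillar 4-leaf trees under one root; its 2520 labelings are the
only 8-or-fewer-leaf cladograms on which the formulas differ, and the
published total mass over the 8-leaf cladograms consequently falls short
of 1 by exactly half their mass. `prob_cladogram_ford_published` is
namespaced as a comparator and is never used by any other code path.

No Markov branching recurrence exists for unordered shape probabilities:
joining a shape with itself forces the factor q_α(m,m), joining it with a
different equal-k shape forces 2q_α(m,m). The demonstration function
searches the m-leaf shapes for an equal-k pair and prints all four exact
probabilities; the smallest m admitting such a pair is 6 (m = 4 and 5 have
one shape per k value, so the function raises there).

## Exact arithmetic

All probabilities are ratios of polynomials in α with rational
coefficients. The package carries them in a dedicated canonical form —
numerator and denominator coprime (polynomial GCD over ℚ), denominator an
integer-coefficient primitive polynomial with positive leading coefficient
— so that equality of probabilities is structural equality of
representations, and identities like the worked example are asserted
bit-exactly. Coefficients are `fractions.Fraction` over arbitrary-precision
integers; no floating point enters symbolic arithmetic. Float α is a
convenience layer: the exact result is computed first (at the exact binary
rational of the float) and converted at the end.

Evaluation reduces before substituting, so removable singularities behave:
at α = 1 both φ_α(1,1) and Γ_α(2) vanish, and any fixed-α fast path
refuses α = 1 and defers to the symbolic route, where the (1 − α) factors
cancel tree by tree. A remaining zero of the denominator is a true pole
and raises an error naming the point.

The canonical ASCII rendering (`2*(1-a)/(4-a)`, factors ordered by root,
ascending) is produced by the package's own formatter via rational-root
factorization; parsing back goes through sympy, and a test cross-checks
every rendered probability against sympy's independent simplification.

## Enumeration and the oracle

Shapes are enumerated by root-split recursion (Wedderburn–Etherington
counts), cladograms by distributing label subsets with the smallest label
anchored to the left subtree ((2n−3)!! counts); both are deterministic and
duplicate-free, verified by brute force at small n. The growth oracle
enumerates all (2n−3)!! insertion histories; for symbolic α the common
denominator ∏_{ℓ=2}^{n−1}(ℓ − α) is factored out so each history only
multiplies linear numerator factors. Oracle equivalence — history masses
vs closed forms — is tested symbolically for n ≤ 7 and at rational α for
n = 8 (135135 histories, about half a minute).

Exhaustive sweeps over the 8-leaf cladograms memoize the closed form on
the split multiset (and, for the comparator, the symmetric-branch count):
the 135135 trees share only 23 shapes, so per-tree work is split
extraction plus a dictionary lookup. These sizes (n ≤ 8 for cladograms and
histories, n ≤ 12 for shape enumeration) were chosen as the range in which
exact exhaustive verification is comfortable on a laptop; the closed-form
functions themselves have no such limit.

## Sampling

The sampler draws insertion positions with exact cumulative weights: the
uniform variate from `numpy.random.default_rng` is converted to its exact
binary rational and compared against Fraction cumulative sums over a fixed
position order (pendant arcs by leaf label, internal arcs in preorder,
then the new-root position), so runs are bit-reproducible given a seed.
`sample_from_model` draws a cladogram from the history law and, for the
cladogram target, applies a uniformly random relabeling — this converts
the history law P′ into the cladogram law P, which spreads each shape's
mass equally over its n!/2^k labelings (P′ does not). α = 1 is supported:
pendant weights vanish and the process produces caterpillars.

Goodness of fit is checked by chi-square against the exact shape law at
n = 5 with 10⁵ draws and fixed seeds, at significance 10⁻⁴, for α ∈
{0, 1/2} (plus 9/10 in the unit suite). These draws emulate the model
itself, not empirical phylogenies; passing them shows the sampler follows
the intended law, not that real trees do.

## Interfaces and conventions

Newick dialect: binary, no branch lengths, no internal labels; shapes use
empty leaf names; the semicolon is required on output and optional on
input. Parsing is delegated to dendropy; because dendropy silently drops
empty-named leaves, shape-mode input is pre-tokenized to give anonymous
leaves unique placeholder names first. Canonical output orders children by
(leaf count, shape encoding, smallest descendant label); the shape
encoding is chosen so that among equal-size siblings the more balanced
subtree prints first. Digit labels compare numerically ("2" before "10"),
other labels lexically.

The CLI (`alphatree prob|enumerate|sample|verify`) is a thin layer over
the library: α parses with rational precedence ("1/3" stays exact,
"0.25" becomes a float), results go to stdout, logs to stderr, and exit
codes are 0 (ok), 1 (invariant violation), 2 (usage). `enumerate` emits a
TSV with an exact footer sum, byte-identical across runs.

## Known limitations

* No parameter inference (estimating α from data), no moments or
  asymptotics of balance indices, no branch lengths, no multifurcations.
* Exhaustive routines are capped (cladograms/histories at n = 8) by
  design; sampling beyond that range works but exactness of the law can
  then only be spot-checked statistically.
* The hypothetical unordered-shape recurrence factor exists only inside
  the refutation report; it is deliberately not an API.
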