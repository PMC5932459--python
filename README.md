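# alphatree

Exact probabilities of cladograms and tree shapes under the α-model of
random phylogenetic tree growth.

The α-model grows a rooted bifurcating tree leaf by leaf: with ℓ leaves
present, the next leaf attaches to one of the ℓ pendant arcs with weight
1 − α each, or to one of the ℓ − 2 internal arcs or above the root with
weight α each (total weight ℓ − α). The parameter α ∈ [0, 1] interpolates
between two classical null models of phylogenetics: α = 0 is the Yule
(pure-birth) model and α = 1/2 the uniform (PDA) model in which all
(2n − 3)!! cladograms on n taxa are equiprobable. These distributions are
the standard references against which the shape of real phylogenies — tree
balance in particular — is judged.

`alphatree` computes the probability of any individual tree under this
model **exactly**, either symbolically as a rational function of α or at a
fixed rational (or float) α, for all four flavors of tree:

| object | law |
|---|---|
| cladogram `T` (leaf-labeled) | `P(T) = 2^(n−1) / (n!·Γ_α(n)) · ∏_{(a,b)∈NS(T)} φ_α(a,b)` |
| tree shape `S` (unlabeled), k symmetric branch points | `P*(S) = 2^(n−k−1)/Γ_α(n) · ∏ φ_α(a,b)` |
| ordered shape | `P°*(S) = ∏ q_α(a,b)` |
| ordered cladogram | `P°(T) = P(T)/2^(n−1)` |

with `Γ_α(n) = ∏_{i=1}^{n−1}(i−α)`,
`φ_α(a,b) = (α/2)·C(a+b,a) + (1−2α)·C(a+b−2,a−1)`,
`q_α(a,b) = Γ_α(a)Γ_α(b)/Γ_α(a+b) · φ_α(a,b)`, and `NS(T)` the multiset of
numerical splits (the pair of descendant-leaf counts at each internal
node).

The widely cited published closed form for `P(T)` uses a doubled kernel
`q̂_α` and is **wrong** on some trees with 8 or more leaves — on the
smallest counterexample it returns exactly half the true probability, and
its total mass over the 8-leaf cladograms falls short of 1. That erroneous
formula is shipped too, clearly separated as a comparator
(`prob_cladogram_ford_published`), so the discrepancy can be reproduced.
The package also includes the growth process itself as a seeded sampler
and as an exhaustive enumerator of insertion histories, which serves as a
brute-force oracle for every closed form.

## Worked example

The smallest cladogram on which the published formula fails:

```python
from fractions import Fraction
from alphatree import parse_newick, prob_cladogram, prob_cladogram_ford_published

t = parse_newick("(((1,2),(3,4)),(((5,6),7),8));", "cladogram")

print(prob_cladogram(t))                    # symbolic, exact
print(prob_cladogram(t, Fraction(1, 2)).numeric)
print(prob_cladogram(t, 0).numeric)
print(prob_cladogram_ford_published(t, Fraction(1, 2)).numeric)
```

prints

```
1/126*(1-a)^2*(2-a)/((3-a)*(5-a)*(6-a)*(7-a))
1/135135
1/39690
1/270270
```

The first line is the exact probability as a function of α (`a` in the
output). At α = 1/2 it equals 1/135135 = 1/(2·8−3)!!, as the uniform model
demands — every 8-leaf cladogram has this probability. At α = 0 it equals
the Yule value 2⁷/8! · 1/(7·3·3·2·1·1·1) = 1/39690. The published formula
(last line) returns half the correct uniform value, which is how the error
was found.

The same numbers fall out of the command line:

```
alphatree prob "(((1,2),(3,4)),(((5,6),7),8));" -a 1/2
alphatree prob "((,),(,(,)));" -d shape          # → 2*(1-a)/(4-a)
alphatree enumerate -n 5 -a 1/4                  # TSV, footer sum exactly 1
alphatree sample -n 6 -a 1/3 -c 10 -s 42
alphatree verify --max-n 6                       # closed forms vs growth oracle
```

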