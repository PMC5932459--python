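"""Shared fixtures.

The expensive object is the exhaustive census of the 135135 cladograms on 8
leaves; it is computed once per session and reused by the normalization,
limit-law and published-formula tests.
"""

from collections import Counter
from fractions import Fraction

import pytest

from alphatree.trees import Cladogram, enumerate_cladograms, parse_newick

COUNTEREXAMPLE8_NEWICK = "(((1,2),(3,4)),(((5,6),7),8));"
EXAMPLE7_NEWICK = "((1,2),(3,((4,5),(6,7))));"


def census(n: int) -> Counter:
    """Count cladograms on {1..n} by (split multiset, k, defect), where
    ``defect`` is the number of internal nodes whose children have equal
    leaf counts but non-isomorphic shapes — exactly where the published
    closed form loses factors of 2."""
    out = Counter()
    for t in enumerate_cladograms(n):
        k = 0
        defect = 0
        for v in t.internal_nodes():
            c1, c2 = v.children
            if c1.n_leaves == c2.n_leaves:
                if c1.shape_key() == c2.shape_key():
                    k += 1
                else:
                    defect += 1
        out[(tuple(t.numerical_splits()), k, defect)] += 1
    return out


@pytest.fixture(scope="session")
def t8_census() -> Counter:
    return census(8)


@pytest.fixture(scope="session")
def counterexample8() -> Cladogram:
    return parse_newick(COUNTEREXAMPLE8_NEWICK, "cladogram")


@pytest.fixture(scope="session")
def example7() -> Cladogram:
    return parse_newick(EXAMPLE7_NEWICK, "cladogram")
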