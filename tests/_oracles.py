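"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: exact
rational arithmetic throughout, direct enumeration instead of closed
forms.
"""

from fractions import Fraction
from math import comb


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> Fraction:
    """P(top-left cell = a) for a 2x2 table with margins
    (row1, row2) x (col1, col2), by counting arrangements."""
    total = row1 + row2
    return Fraction(comb(col1, a) * comb(total - col1, row1 - a), comb(total, row1))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration of all tables with
    the observed margins, summing point probabilities <= the observed
    one (minimum-likelihood convention, exact rational comparison)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    pmf = {x: hypergeom_pmf(x, row1, row2, col1) for x in range(lo, hi + 1)}
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed)


def hypergeom_tail_exact(k: int, universe: int, marked: int, drawn: int) -> Fraction:
    """P(overlap >= k) when drawing ``drawn`` genes from ``universe``
    of which ``marked`` are regulon members, by direct summation."""
    total = Fraction(0)
    for x in range(k, min(marked, drawn) + 1):
        total += Fraction(
            comb(marked, x) * comb(universe - marked, drawn - x),
            comb(universe, drawn),
        )
    return total
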