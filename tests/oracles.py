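"""Independent brute-force oracles used to freeze expected values.

Everything here is computed with exact rational arithmetic
(fractions.Fraction over math.comb), fully independently of the package's
log-space implementations.
"""

from fractions import Fraction
from math import comb


def binomial_two_sided_oracle(k: int, n: int) -> float:
    """Two-sided binomial(n, 1/2) p-value by full enumeration: sum of point
    masses not exceeding the observed mass."""
    masses = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
    obs = masses[k]
    return float(sum(m for m in masses if m <= obs))


def binomial_lower_tail_oracle(k: int, n: int) -> float:
    """One-sided (lower tail) binomial(n, 1/2) p-value by enumeration."""
    return float(sum(Fraction(comb(n, i), 2**n) for i in range(k + 1)))


def hwe_exact_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test by full enumeration over all
    heterozygote counts compatible with the observed allele counts."""
    n = n_homref + n_het + n_homalt
    n_alt = 2 * n_homalt + n_het
    n_ref = 2 * n_homref + n_het
    m = min(n_alt, n_ref)
    weights = {}
    for het in range(m % 2, m + 1, 2):
        ha = (n_alt - het) // 2
        hr = (n_ref - het) // 2
        # multinomial coefficient x 2^het; the constant factor cancels on
        # normalisation
        w = Fraction(
            comb(n, hr) * comb(n - hr, het) * (2**het)
        )
        weights[het] = w
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test by enumeration over all 2x2 tables with
    the observed margins, summing hypergeometric masses <= the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)
    masses = {}
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        masses[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    obs = masses[a]
    return float(sum(m for m in masses.values() if m <= obs))


def single_stratum_mh_chi2_oracle(a: int, b: int, c: int, d: int) -> float:
    """1-df Mantel-Haenszel chi-square for one 2x2 table from the E/V
    closed forms, hand-coded."""
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    return (a - e) ** 2 / v


def recessive_carrier_oracle(dosages) -> bool:
    """Direct statement of the recessive carrier rule."""
    ds = [d for d in dosages if d is not None]
    return any(d == 2 for d in ds) or sum(1 for d in ds if d == 1) >= 2
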