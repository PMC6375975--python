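"""Independent oracles used by the test suite.

Everything here is computed with exact rational arithmetic and brute-force
enumeration, deliberately sharing no code path with the package's log-gamma
implementation.
"""

from fractions import Fraction
from math import comb


def urn_pmf(k: int, s: int, a: Fraction) -> dict:
    """Exact pmf of red draws from a Pólya urn by enumerating draw sequences.

    The urn starts with 1 red and k-1 black balls; each draw returns the ball
    plus ``a`` balls of its colour; s draws are made.  Returns
    {number of red draws: exact probability}.
    """
    a = Fraction(a)
    out: dict[int, Fraction] = {}

    def rec(draws_left: int, reds: int, red_mass: Fraction, black_mass: Fraction,
            prob: Fraction) -> None:
        if draws_left == 0:
            out[reds] = out.get(reds, Fraction(0)) + prob
            return
        total = red_mass + black_mass
        if red_mass > 0:
            rec(draws_left - 1, reds + 1, red_mass + a, black_mass,
                prob * red_mass / total)
        if black_mass > 0:
            rec(draws_left - 1, reds, red_mass, black_mass + a,
                prob * black_mass / total)

    rec(s, 0, Fraction(1), Fraction(k - 1), Fraction(1))
    return out


def urn_survival(w: int, k: int, s: int, a: Fraction) -> Fraction:
    """Exact P(at least w red draws) from the enumeration oracle."""
    pmf = urn_pmf(k, s, a)
    return sum((p for x, p in pmf.items() if x >= w), Fraction(0))


def binom_pmf(x: int, s: int, k: int) -> Fraction:
    """Exact Binomial(s, 1/k) mass: the a = 0 limit."""
    return Fraction(comb(s, x)) * Fraction(k - 1) ** (s - x) / Fraction(k) ** s


def binom_survival(w: int, s: int, k: int) -> Fraction:
    return sum((binom_pmf(x, s, k) for x in range(w, s + 1)), Fraction(0))
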