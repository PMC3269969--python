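"""Closed-form instance statistics for planted motif search over DNA.

For random l-mers u, x the single-pair match probability is

    p_{l,d} = P(d_H(u, x) <= d) = sum_{i=0}^{d} C(l, i) (3/4)^i (1/4)^{l-i},

so the expected size of the common d-neighborhood of three independent
uniform l-mers is E|B_d(x, y, z)| = 4^l p_{l,d}^3 -- the quantity that
governs the search's expected running time.

For a random l-mer w against an instance with n sequences of length m:

    P  = p_{l,d}                        (one window matches)
    Q' = (1 - P)^(m - l + 1)            (no window of one sequence matches)
    Q  = 1 - Q'                         (some window matches)
    R  = sum_{i=q}^{n} C(n, i) Q^i (1 - Q)^(n - i)   (>= q sequences match)

and the expected number of motifs arising by chance is 4^l R.  The window
independence behind Q' is an approximation (overlapping windows are
correlated), but it is the standard one and is accurate at these scales.
An instance (l, d) is called *challenging* when d is the smallest mismatch
budget for which 4^l R >= 1.

Binomial tails are summed exactly (no normal approximation); match
probabilities are built from exact integer combinatorics before conversion
to float.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .neighborhood import neighborhood_size


def match_probability(l: int, d: int) -> float:
    """p_{l,d}: chance two independent uniform DNA l-mers are within d."""
    if not 0 <= d <= l:
        raise ValueError(f"d={d} must be in [0, l={l}]")
    return neighborhood_size(l, d, 4) / 4**l


def expected_intersection_size(l: int, d: int) -> float:
    """E|B_d(x, y, z)| = 4^l p_{l,d}^3 for independent uniform l-mers."""
    return 4**l * match_probability(l, d) ** 3


def sequence_hit_probability(l: int, d: int, m: int) -> float:
    """Q: chance a random l-mer is within d of some window of a length-m
    random sequence (windows treated as independent)."""
    if l > m:
        raise ValueError(f"l={l} exceeds m={m}")
    p = match_probability(l, d)
    return 1.0 - (1.0 - p) ** (m - l + 1)


def expected_chance_motifs(l: int, d: int, n: int, m: int, q: int) -> float:
    """4^l R: expected number of spurious (l, d)-motifs at quorum q."""
    if not 1 <= q <= n:
        raise ValueError(f"q={q} must be in [1, n={n}]")
    big_q = sequence_hit_probability(l, d, m)
    r = sum(
        comb(n, i) * big_q**i * (1.0 - big_q) ** (n - i) for i in range(q, n + 1)
    )
    return 4**l * r


def challenging_d(l: int, n: int, m: int, q: int) -> int:
    """Smallest d whose expected chance-motif count reaches 1.

    Always terminates: at d = l every l-mer matches everywhere, so the
    expectation is 4^l >= 1.
    """
    for d in range(l + 1):
        if expected_chance_motifs(l, d, n, m, q) >= 1.0:
            return d
    raise AssertionError("unreachable: d = l always qualifies")


@dataclass(frozen=True)
class InstanceStatistics:
    """All closed-form quantities for one (l, d, n, m, q) configuration."""

    l: int
    d: int
    n: int
    m: int
    q: int
    p_match: float
    hit_probability: float  # Q
    miss_probability: float  # Q'
    quorum_probability: float  # R
    expected_chance_motifs: float  # 4^l R
    expected_intersection: float  # 4^l p^3
    neighborhood: int  # N(l, d)


def instance_statistics(l: int, d: int, n: int, m: int, q: int) -> InstanceStatistics:
    p = match_probability(l, d)
    big_q = sequence_hit_probability(l, d, m)
    return InstanceStatistics(
        l=l,
        d=d,
        n=n,
        m=m,
        q=q,
        p_match=p,
        hit_probability=big_q,
        miss_probability=1.0 - big_q,
        quorum_probability=expected_chance_motifs(l, d, n, m, q) / 4**l,
        expected_chance_motifs=expected_chance_motifs(l, d, n, m, q),
        expected_intersection=expected_intersection_size(l, d),
        neighborhood=neighborhood_size(l, d, 4),
    )


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
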