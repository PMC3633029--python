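"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's analytic machinery: section
probabilities are obtained by exhaustively enumerating every possible section
(all C(M, m) cell subsets) and every founder-type assignment (all 2**n type
vectors).  Feasible only for tiny GCs, which is the point.
"""

from __future__ import annotations

import math
from itertools import combinations, product


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def enumerate_section_probs(
    M: int,
    m: int,
    n: int,
    p: float,
    l_TA: int,
    l_TB: int,
) -> tuple[list[float], list[float], tuple[float, float, float]]:
    """Exhaustive pure-section probabilities for a tiny GC.

    Returns (P_A_by_k, P_B_by_k, (f_A, f_B, f_Mix)) where P_X_by_k[k] is the
    probability that a GC seeded by exactly k type-B founders yields a
    section scored pure-X, summed over all founder-type assignments with that
    k (weight p^k q^(n-k) each).
    """
    q = 1.0 - p
    P_A = [0.0] * (n + 1)
    P_B = [0.0] * (n + 1)
    for types in product((0, 1), repeat=n):  # 1 = type-B founder
        k = sum(types)
        weight = p**k * q ** (n - k)
        r = _round_half_up(k * M / n)  # expanded type-B cells
        n_sections = 0
        n_scored_A = 0
        n_scored_B = 0
        for section in combinations(range(M), m):
            n_b = sum(1 for cell in section if cell < r)
            n_a = m - n_b
            n_sections += 1
            if n_b <= l_TB:
                n_scored_A += 1
            if n_a <= l_TA:
                n_scored_B += 1
        P_A[k] += weight * n_scored_A / n_sections
        P_B[k] += weight * n_scored_B / n_sections
    # pure-A total excludes k = n, pure-B excludes k = 0 (those terms are
    # zero whenever l_T < m, but the exclusion mirrors the model definition)
    f_A = sum(P_A[:n])
    f_B = sum(P_B[1:])
    return P_A, P_B, (f_A, f_B, 1.0 - f_A - f_B)
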