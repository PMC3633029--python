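"""Analytic section-classification probabilities for two-phenotype chimeric GCs.

Two model levels are provided:

* the *basic* model — a GC is founded by ``n`` cells drawn from a pool with
  phenotype-B fraction ``p``; a whole GC is observed, so the pure-A / pure-B /
  mixed fractions are simply ``(q**n, p**n, 1 - q**n - p**n)``;
* the *extended* model — only a section of ``m`` of the ``M`` GC cells is
  observed (hypergeometric sampling) and up to ``l_TB`` type-B (resp. ``l_TA``
  type-A) cells may be overlooked when scoring a section pure-A (resp.
  pure-B), with the founder number either fixed or Poisson-distributed.

All binomial coefficients are evaluated through scipy's log-space binomial and
hypergeometric routines; inner hypergeometric sums are cumulative-distribution
values and therefore stay in [0, 1] by construction.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats

from .types import (
    ChimeraMix,
    FractionTriple,
    ScoringThresholds,
    SectionGeometry,
    round_half_up,
)

__all__ = [
    "basic_expected_fractions",
    "invert_founders",
    "pure_A_section_prob",
    "pure_B_section_prob",
    "fixed_n_fractions",
    "poisson_fractions",
    "find_lambda_crossing",
    "poisson_truncation_point",
]

#: hard cap on the Poisson founder-number summation
POISSON_N_CAP = 500

_R_MODES = ("floor", "nearest", "ceil")


def _round_r(x: float, mode: str) -> int:
    if mode == "nearest":
        return round_half_up(x)
    if mode == "floor":
        return int(np.floor(x))
    if mode == "ceil":
        return int(np.ceil(x))
    raise ValueError(f"unknown rounding mode {mode!r}; expected one of {_R_MODES}")


def basic_expected_fractions(n: float, mix: ChimeraMix) -> FractionTriple:
    """Pure-A / pure-B / mixed GC fractions for ``n`` founders, no sampling.

    ``n`` may be real-valued: the inversion of an observed pure fraction gives
    a non-integer founder estimate which is only rounded for reporting.
    """
    if not n > 0:
        raise ValueError(f"founder count must be positive, got {n}")
    f_A = mix.q**n
    f_B = mix.p**n
    return FractionTriple(f_A=f_A, f_B=f_B, f_Mix=1.0 - f_A - f_B)


def invert_founders(f_pure_observed: float, base: float) -> float:
    """Founder count solving ``base**n == f_pure_observed``.

    Returns the real-valued ``log(f) / log(base)``; callers round to the
    nearest integer for reporting.
    """
    for name, v in (("f_pure_observed", f_pure_observed), ("base", base)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
    return float(np.log(f_pure_observed) / np.log(base))


@lru_cache(maxsize=128)
def _hyp_cdf_table(M: int, m: int, threshold: int) -> np.ndarray:
    """P(X <= threshold) for X ~ Hypergeom(M, r, m), tabulated over r = 0..M.

    The table is the inner sum of the pure-section probabilities: the chance
    that a section of ``m`` cells drawn from a GC with ``r`` marked cells
    contains at most ``threshold`` of them.
    """
    r = np.arange(M + 1)
    table = stats.hypergeom.cdf(threshold, M, r, m)
    table.setflags(write=False)
    return table


def _pure_section_factor(r: int, geom: SectionGeometry, threshold: int) -> float:
    """Probability that a section from a GC with ``r`` minority cells hides them."""
    return float(_hyp_cdf_table(geom.M, geom.m, threshold)[r])


def _check_k(n: int, k: int) -> None:
    if int(n) != n or n < 1:
        raise ValueError(f"extended-model founder count must be integer >= 1, got {n}")
    if int(k) != k or not 0 <= k <= n:
        raise ValueError(f"k={k} out of range [0, {n}]")


def pure_A_section_prob(
    n: int,
    k: int,
    mix: ChimeraMix,
    geom: SectionGeometry,
    thresholds: ScoringThresholds,
    r_mode: str = "nearest",
) -> float:
    """Probability that a GC seeded by ``k`` type-B founders (of ``n``) yields
    a section scored pure-A.

    The binomial seeding weight ``C(n,k) p^k q^(n-k)`` multiplies the chance
    that the section contains at most ``l_TB`` of the GC's ``r`` type-B cells,
    where ``r`` is ``k*M/n`` rounded per ``r_mode``.  An empty summation range
    (the section cannot avoid more than ``l_TB`` type-B cells) gives 0.
    """
    _check_k(n, k)
    thresholds.validate_for(geom)
    r = _round_r(k * geom.M / n, r_mode)
    weight = stats.binom.pmf(k, n, mix.p)
    return float(weight * _pure_section_factor(r, geom, thresholds.l_TB))


def pure_B_section_prob(
    n: int,
    k: int,
    mix: ChimeraMix,
    geom: SectionGeometry,
    thresholds: ScoringThresholds,
    r_mode: str = "nearest",
) -> float:
    """Probability that a GC seeded by ``k`` type-B founders yields a section
    scored pure-B (at most ``l_TA`` type-A cells present in the section)."""
    _check_k(n, k)
    thresholds.validate_for(geom)
    r = _round_r(k * geom.M / n, r_mode)
    s = geom.M - r
    weight = stats.binom.pmf(k, n, mix.p)
    return float(weight * _pure_section_factor(s, geom, thresholds.l_TA))


@lru_cache(maxsize=200_000)
def _fixed_triple(
    n: int,
    p: float,
    M: int,
    m: int,
    l_TA: int,
    l_TB: int,
    r_mode: str,
) -> tuple[float, float, float]:
    """Cached (f_A, f_B, f_Mix) for the fixed-n extended model."""
    k = np.arange(n + 1)
    weights = stats.binom.pmf(k, n, p)
    if r_mode == "nearest":
        r = np.floor(k * M / n + 0.5).astype(np.int64)
    elif r_mode == "floor":
        r = np.floor(k * M / n).astype(np.int64)
    elif r_mode == "ceil":
        r = np.ceil(k * M / n).astype(np.int64)
    else:
        raise ValueError(f"unknown rounding mode {r_mode!r}")
    s = M - r
    hide_B = _hyp_cdf_table(M, m, l_TB)
    hide_A = _hyp_cdf_table(M, m, l_TA)
    # pure-A sums k = 0..n-1; pure-B sums k = 1..n (a truly pure GC of the
    # opposite type is never scored pure for this one).
    f_A = float(np.sum(weights[:n] * hide_B[r[:n]]))
    f_B = float(np.sum(weights[1:] * hide_A[s[1:]]))
    return (f_A, f_B, 1.0 - f_A - f_B)


def fixed_n_fractions(
    n: int,
    mix: ChimeraMix,
    geom: SectionGeometry,
    thresholds: ScoringThresholds,
    r_mode: str = "nearest",
) -> FractionTriple:
    """Section-classification fractions for exactly ``n`` founders.

    With ``m == M`` and zero thresholds this reduces exactly to
    :func:`basic_expected_fractions`.  Components sum to 1.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"extended-model founder count must be integer >= 1, got {n}")
    thresholds.validate_for(geom)
    f_A, f_B, f_Mix = _fixed_triple(
        int(n), mix.p, geom.M, geom.m, thresholds.l_TA, thresholds.l_TB, r_mode
    )
    return FractionTriple(f_A=f_A, f_B=f_B, f_Mix=f_Mix)


def poisson_truncation_point(lam: float, tail_tol: float = 1e-12) -> int:
    """Smallest n with cumulative Poisson mass >= 1 - tail_tol (capped)."""
    n_max = int(stats.poisson.ppf(1.0 - tail_tol, lam))
    while stats.poisson.cdf(n_max, lam) < 1.0 - tail_tol and n_max < POISSON_N_CAP:
        n_max += 1
    return min(max(n_max, 1), POISSON_N_CAP)


def poisson_fractions(
    lam: float,
    mix: ChimeraMix,
    geom: SectionGeometry,
    thresholds: ScoringThresholds,
    tail_tol: float = 1e-12,
    r_mode: str = "nearest",
) -> FractionTriple:
    """Section fractions with Poisson(lam) founder numbers.

    The n = 0 term (an unseeded GC) is omitted and the triple is *not*
    renormalized, so the components sum to ``1 - exp(-lam)`` within
    ``tail_tol``.
    """
    if not lam > 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    thresholds.validate_for(geom)
    n_max = poisson_truncation_point(lam, tail_tol)
    ns = np.arange(1, n_max + 1)
    pmf = stats.poisson.pmf(ns, lam)
    triples = np.array(
        [
            _fixed_triple(
                int(n), mix.p, geom.M, geom.m, thresholds.l_TA, thresholds.l_TB, r_mode
            )
            for n in ns
        ]
    )
    F_A, F_B, F_Mix = pmf @ triples
    return FractionTriple(f_A=float(F_A), f_B=float(F_B), f_Mix=float(F_Mix))


def find_lambda_crossing(
    target_F_A: float,
    mix: ChimeraMix,
    geom: SectionGeometry,
    thresholds: ScoringThresholds,
    bracket: tuple[float, float] = (0.5, 100.0),
    f_tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Mean founder number lambda* at which F_A(lambda) equals ``target_F_A``.

    F_A is decreasing in lambda over the bracket (asserted numerically), so
    plain bisection converges; iteration stops once |F_A - target| < f_tol.
    """
    lo, hi = bracket

    def f_A(lam: float) -> float:
        return poisson_fractions(lam, mix, geom, thresholds).f_A

    f_lo, f_hi = f_A(lo), f_A(hi)
    if not f_lo > f_hi:
        raise ValueError("F_A is not decreasing over the bracket")
    if not (f_hi <= target_F_A <= f_lo):
        raise ValueError(
            f"target {target_F_A} not bracketed by F_A range [{f_hi}, {f_lo}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f_A(mid)
        if abs(f_mid - target_F_A) < f_tol:
            return mid
        if f_mid > target_F_A:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
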