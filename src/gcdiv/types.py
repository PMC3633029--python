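"""Shared domain records for the germinal-center diversity model.

All records are light, validated dataclasses; they carry no behaviour beyond
construction-time invariant checks and small convenience accessors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ChimeraMix",
    "SectionGeometry",
    "ScoringThresholds",
    "SeedingModel",
    "GCComposition",
    "FractionTriple",
    "ObservedSectionData",
    "AbundanceSample",
    "DiversityEstimate",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    ``numpy.rint`` rounds halves to even; cell counts here follow the
    half-away-from-zero convention (all quantities are non-negative).
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ChimeraMix:
    """Mixing fractions of the two B-cell phenotypes in the seeding pool.

    ``p`` is the fraction of phenotype-B cells; ``q = 1 - p`` is the
    phenotype-A fraction, derived so that ``p + q == 1`` holds exactly.
    """

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class SectionGeometry:
    """GC size ``M`` (total B cells) and section size ``m`` (B cells/section)."""

    M: int
    m: int

    def __post_init__(self) -> None:
        if int(self.M) != self.M or int(self.m) != self.m:
            raise ValueError("M and m must be integers")
        object.__setattr__(self, "M", int(self.M))
        object.__setattr__(self, "m", int(self.m))
        if self.M < 1 or self.m < 1:
            raise ValueError("M and m must be positive")
        if self.m > self.M:
            raise ValueError(f"section size m={self.m} exceeds GC size M={self.M}")


@dataclass(frozen=True)
class ScoringThresholds:
    """Scoring-error limits, in cells.

    ``l_TB`` is the maximum number of type-B cells that can be overlooked in a
    section scored pure-A; ``l_TA`` the converse.  ``l_TA + l_TB < m`` is
    required (checked against a geometry via :meth:`validate_for`), otherwise
    a section could be scored pure for both types at once.
    """

    l_TA: int
    l_TB: int

    def __post_init__(self) -> None:
        if int(self.l_TA) != self.l_TA or int(self.l_TB) != self.l_TB:
            raise ValueError("thresholds must be integer cell counts")
        object.__setattr__(self, "l_TA", int(self.l_TA))
        object.__setattr__(self, "l_TB", int(self.l_TB))
        if self.l_TA < 0 or self.l_TB < 0:
            raise ValueError("thresholds must be non-negative")

    def validate_for(self, geom: SectionGeometry) -> None:
        if self.l_TA + self.l_TB >= geom.m:
            raise ValueError(
                f"degenerate thresholds: l_TA + l_TB = {self.l_TA + self.l_TB} "
                f">= m = {geom.m} (a section could score pure for both types)"
            )

    @classmethod
    def from_percent(
        cls, l_TA_pct: float, l_TB_pct: float, m: int
    ) -> "ScoringThresholds":
        """Convert percent-of-section thresholds to cell counts.

        Cells = round(pct * m / 100), halves away from zero.
        """
        return cls(
            l_TA=round_half_up(l_TA_pct * m / 100.0),
            l_TB=round_half_up(l_TB_pct * m / 100.0),
        )


@dataclass(frozen=True)
class SeedingModel:
    """Founder-number model: a fixed count ``n`` or Poisson with mean ``lam``."""

    mode: str  # "fixed" | "poisson"
    n: Optional[int] = None
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.n is None or int(self.n) != self.n or self.n < 1:
                raise ValueError("fixed mode requires integer n >= 1")
            object.__setattr__(self, "n", int(self.n))
        elif self.mode == "poisson":
            if self.lam is None or not self.lam > 0:
                raise ValueError("poisson mode requires lam > 0")
        else:
            raise ValueError(f"unknown seeding mode {self.mode!r}")

    @classmethod
    def fixed(cls, n: int) -> "SeedingModel":
        return cls(mode="fixed", n=n)

    @classmethod
    def poisson(cls, lam: float) -> "SeedingModel":
        return cls(mode="poisson", lam=lam)


@dataclass(frozen=True)
class GCComposition:
    """Expanded composition of a GC seeded by ``k`` type-B founders out of ``n``.

    ``r`` type-B and ``s`` type-A cells with ``r + s = M`` and ``r`` the
    nearest integer (half away from zero) to ``k * M / n``.
    """

    n: int
    k: int
    M: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k={self.k} out of range [0, {self.n}]")

    @property
    def r(self) -> int:
        return round_half_up(self.k * self.M / self.n)

    @property
    def s(self) -> int:
        return self.M - self.r


@dataclass(frozen=True)
class FractionTriple:
    """Fractions of sections scored pure-A, pure-B and mixed.

    Under the fixed-n model the components sum to 1; under the Poisson model
    they sum to ``1 - exp(-lam)`` (the n = 0 term is omitted, not
    renormalized).
    """

    f_A: float
    f_B: float
    f_Mix: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_A, self.f_B, self.f_Mix)

    def as_percent(self) -> tuple[float, float, float]:
        return (100.0 * self.f_A, 100.0 * self.f_B, 100.0 * self.f_Mix)

    @property
    def total(self) -> float:
        return self.f_A + self.f_B + self.f_Mix


@dataclass(frozen=True)
class ObservedSectionData:
    """Observed percentages of sections scored pure-A / pure-B / mixed."""

    pct_A: float
    pct_B: float
    pct_Mix: float
    mix: ChimeraMix
    n_sections: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("pct_A", "pct_B", "pct_Mix"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        total = self.pct_A + self.pct_B + self.pct_Mix
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"section percentages must sum to 100 (within 0.5), got {total}"
            )

    @classmethod
    def from_fractions(
        cls,
        f_A: float,
        f_B: float,
        f_Mix: float,
        mix: ChimeraMix,
        n_sections: Optional[int] = None,
    ) -> "ObservedSectionData":
        return cls(100.0 * f_A, 100.0 * f_B, 100.0 * f_Mix, mix, n_sections)

    def as_percent_tuple(self) -> tuple[float, float, float]:
        return (self.pct_A, self.pct_B, self.pct_Mix)


@dataclass(frozen=True)
class AbundanceSample:
    """Clone counts observed within one GC sample."""

    counts: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise ValueError("empty abundance sample")
        if any(c < 1 for c in counts):
            raise ValueError("all clone counts must be >= 1")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, counts: Sequence[int], name: str = "") -> "AbundanceSample":
        return cls(counts=tuple(int(c) for c in counts), name=name)

    @property
    def S_obs(self) -> int:
        """Number of distinct clones observed."""
        return len(self.counts)

    @property
    def N(self) -> int:
        """Total number of sampled cells/sequences."""
        return int(sum(self.counts))

    @property
    def f_k(self) -> dict[int, int]:
        """Frequency-of-frequencies histogram: clones seen exactly k times."""
        return dict(sorted(Counter(self.counts).items()))

    def counts_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class DiversityEstimate:
    """Result of a richness estimation for one abundance sample."""

    method: str  # "yule" | "ace" | "chao1"
    D_hat: float
    S_obs: int
    rho_hat: Optional[float] = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    log_likelihood: Optional[float] = None
    iterations: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.D_hat < self.S_obs - 1e-9:
            raise ValueError(
                f"estimated diversity {self.D_hat} below observed {self.S_obs}"
            )
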