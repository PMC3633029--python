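"""Chi-square consistency statistics and grid-search fitting.

The chi-square statistic is computed on the *percent* scale (0-100); this is
the convention under which the classic consistency analysis of the p = 0.21
chimera dataset yields its published values (132.6 and ~1.62e5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import chimera_model
from .types import (
    ObservedSectionData,
    ScoringThresholds,
    SectionGeometry,
)

__all__ = [
    "ChiSquareResult",
    "ConsistencyReport",
    "GridSearchResult",
    "chi_square_percent",
    "table1_consistency_report",
    "chi2_at_point",
    "grid_search",
    "CRITICAL_P001_DF1",
    "CRITICAL_P001_DF2",
]

#: chi-square critical values at p = 0.001
CRITICAL_P001_DF1 = 10.827
CRITICAL_P001_DF2 = 13.815

CATEGORIES = ("A", "B", "Mix")


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    contributions: dict[str, float]
    critical_value: float
    expected: dict[str, float]
    observed: dict[str, float]

    @property
    def significant(self) -> bool:
        """True when the model is rejected at p = 0.001."""
        return self.chi2 > self.critical_value

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "contributions": dict(self.contributions),
            "critical_value": self.critical_value,
            "significant": self.significant,
            "expected": dict(self.expected),
            "observed": dict(self.observed),
        }


def chi_square_percent(
    observed: Sequence[float],
    expected: Sequence[float],
    include: Optional[Sequence[bool]] = None,
    labels: Sequence[str] = CATEGORIES,
    df: Optional[int] = None,
) -> ChiSquareResult:
    """Sum of (obs - exp)^2 / exp over the included categories, percent scale.

    A category whose expected value was pinned to the observed one (the
    fitted category of a consistency table) contributes exactly zero, so
    including or masking it changes nothing but the default df.
    """
    observed = [float(v) for v in observed]
    expected = [float(v) for v in expected]
    if len(observed) != len(expected) or len(observed) != len(labels):
        raise ValueError("observed/expected/labels length mismatch")
    if include is None:
        include = [True] * len(observed)
    contributions: dict[str, float] = {}
    for lab, obs, exp, inc in zip(labels, observed, expected, include):
        if not inc:
            continue
        if exp <= 0:
            raise ValueError(f"expected value for category {lab!r} must be > 0")
        contributions[lab] = (obs - exp) ** 2 / exp
    n_inc = len(contributions)
    if df is None:
        df = max(n_inc - 1, 1)
    critical = CRITICAL_P001_DF1 if df == 1 else CRITICAL_P001_DF2
    return ChiSquareResult(
        chi2=float(sum(contributions.values())),
        df=df,
        contributions=contributions,
        critical_value=critical,
        expected={lab: e for lab, e in zip(labels, expected)},
        observed={lab: o for lab, o in zip(labels, observed)},
    )


@dataclass(frozen=True)
class ConsistencyReport:
    """Basic-model internal-consistency analysis of one observed dataset.

    For each reference category (the observed pure-A or pure-B fraction) the
    founder number is obtained by inversion, the remaining two categories are
    predicted, and the deviation is scored by chi-square against the 1-df
    critical value at p = 0.001.
    """

    data: ObservedSectionData
    n_from_A: float
    n_from_B: float
    expected_from_A: dict[str, float]
    expected_from_B: dict[str, float]
    chi2_from_A: ChiSquareResult
    chi2_from_B: ChiSquareResult

    def to_dict(self) -> dict:
        return {
            "observed_pct": dict(
                zip(CATEGORIES, self.data.as_percent_tuple())
            ),
            "p": self.data.mix.p,
            "reference_A": {
                "n": self.n_from_A,
                "n_rounded": round(self.n_from_A),
                "expected_pct": dict(self.expected_from_A),
                "chi2": self.chi2_from_A.to_dict(),
            },
            "reference_B": {
                "n": self.n_from_B,
                "n_rounded": round(self.n_from_B),
                "expected_pct": dict(self.expected_from_B),
                "chi2": self.chi2_from_B.to_dict(),
            },
        }

    def to_text(self) -> str:
        lines = [
            "Internal-consistency analysis (basic model)",
            f"  p = {self.data.mix.p:g}, observed A/B/Mix % = "
            f"{self.data.pct_A:g} / {self.data.pct_B:g} / {self.data.pct_Mix:g}",
        ]
        for tag, n, exp, res in (
            ("A", self.n_from_A, self.expected_from_A, self.chi2_from_A),
            ("B", self.n_from_B, self.expected_from_B, self.chi2_from_B),
        ):
            lines.append(
                f"  reference f_{tag}: n = {n:.4f} (~{round(n)}); expected % "
                + ", ".join(f"{k}={v:.6g}" for k, v in exp.items())
                + f"; chi2 = {res.chi2:.6g} (df={res.df}, "
                f"crit={res.critical_value}, "
                f"{'REJECTED' if res.significant else 'consistent'})"
            )
        return "\n".join(lines)


def table1_consistency_report(data: ObservedSectionData) -> ConsistencyReport:
    """Check whether observed section percentages fit the basic binomial model.

    Taking the observed pure-A fraction as reference fixes
    ``n = log_q(f_A_obs)``; the expected pure-B and mixed percentages follow
    from the basic model and are chi-squared against the observations
    (1 df, fitted category contributing zero).  Symmetrically for pure-B.
    """
    mix = data.mix
    f_A_obs = data.pct_A / 100.0
    f_B_obs = data.pct_B / 100.0

    n_A = chimera_model.invert_founders(f_A_obs, mix.q)
    exp_B_given_A = 100.0 * mix.p**n_A
    exp_Mix_given_A = 100.0 * (1.0 - f_A_obs - mix.p**n_A)
    expected_from_A = {
        "A": data.pct_A,
        "B": exp_B_given_A,
        "Mix": exp_Mix_given_A,
    }
    chi2_A = chi_square_percent(
        data.as_percent_tuple(),
        (expected_from_A["A"], expected_from_A["B"], expected_from_A["Mix"]),
        include=(False, True, True),
        df=1,
    )

    n_B = chimera_model.invert_founders(f_B_obs, mix.p)
    exp_A_given_B = 100.0 * mix.q**n_B
    exp_Mix_given_B = 100.0 * (1.0 - f_B_obs - mix.q**n_B)
    expected_from_B = {
        "A": exp_A_given_B,
        "B": data.pct_B,
        "Mix": exp_Mix_given_B,
    }
    chi2_B = chi_square_percent(
        data.as_percent_tuple(),
        (expected_from_B["A"], expected_from_B["B"], expected_from_B["Mix"]),
        include=(True, False, True),
        df=1,
    )

    return ConsistencyReport(
        data=data,
        n_from_A=n_A,
        n_from_B=n_B,
        expected_from_A=expected_from_A,
        expected_from_B=expected_from_B,
        chi2_from_A=chi2_A,
        chi2_from_B=chi2_B,
    )


def chi2_at_point(
    lam: float,
    l_TB_pct: float,
    l_TA_pct: float,
    data: ObservedSectionData,
    geom: SectionGeometry,
    tail_tol: float = 1e-12,
    r_mode: str = "nearest",
) -> ChiSquareResult:
    """Chi-square (3 categories, percent scale) of the extended Poisson model
    at one (lambda, l_TB%, l_TA%) parameter point against observed data."""
    thresholds = ScoringThresholds.from_percent(l_TA_pct, l_TB_pct, geom.m)
    triple = chimera_model.poisson_fractions(
        lam, data.mix, geom, thresholds, tail_tol=tail_tol, r_mode=r_mode
    )
    return chi_square_percent(
        data.as_percent_tuple(), triple.as_percent(), df=2
    )


@dataclass(frozen=True)
class GridSearchResult:
    lambdas: tuple[int, ...]
    l_TB_pcts: tuple[int, ...]
    l_TA_pcts: tuple[int, ...]
    chi2_surface: np.ndarray  # shape (len(lambdas), len(l_TB), len(l_TA)); NaN = skipped
    global_minimum: dict
    local_minima: tuple[dict, ...]
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "axes": {
                "lambda": list(self.lambdas),
                "l_TB_pct": list(self.l_TB_pcts),
                "l_TA_pct": list(self.l_TA_pcts),
            },
            "global_minimum": dict(self.global_minimum),
            "local_minima": [dict(mn) for mn in self.local_minima],
            "n_skipped": self.n_skipped,
        }

    def surface_records(self) -> Iterable[dict]:
        for i, lam in enumerate(self.lambdas):
            for j, ltb in enumerate(self.l_TB_pcts):
                for k, lta in enumerate(self.l_TA_pcts):
                    v = self.chi2_surface[i, j, k]
                    if math.isnan(v):
                        continue
                    yield {
                        "lambda": lam,
                        "l_TB_pct": ltb,
                        "l_TA_pct": lta,
                        "chi2": float(v),
                    }


def _local_minima(surface: np.ndarray, axes: tuple) -> list[dict]:
    """Grid points whose chi2 is <= all (up to 6) axis-adjacent neighbours."""
    minima = []
    shape = surface.shape
    for idx in np.ndindex(shape):
        v = surface[idx]
        if math.isnan(v):
            continue
        is_min = True
        for ax in range(3):
            for step in (-1, 1):
                nb = list(idx)
                nb[ax] += step
                if not 0 <= nb[ax] < shape[ax]:
                    continue
                w = surface[tuple(nb)]
                if not math.isnan(w) and w < v:
                    is_min = False
                    break
            if not is_min:
                break
        if is_min:
            lam_ax, ltb_ax, lta_ax = axes
            minima.append(
                {
                    "lambda": lam_ax[idx[0]],
                    "l_TB_pct": ltb_ax[idx[1]],
                    "l_TA_pct": lta_ax[idx[2]],
                    "chi2": float(v),
                }
            )
    minima.sort(key=lambda d: d["chi2"])
    return minima


def grid_search(
    data: ObservedSectionData,
    geom: SectionGeometry,
    lambda_range: Sequence[int] = tuple(range(1, 41)),
    l_TB_pct_range: Sequence[int] = tuple(range(10, 16)),
    l_TA_pct_range: Sequence[int] = tuple(range(50, 66)),
    tail_tol: float = 1e-12,
    r_mode: str = "nearest",
) -> GridSearchResult:
    """Exhaustive chi-square evaluation over a (lambda, l_TB%, l_TA%) grid.

    Grid points whose percent thresholds convert to a degenerate cell
    configuration (l_TA + l_TB >= m) are skipped (NaN in the surface) and
    counted.  Returns the full surface, the global minimum, and all local
    minima (points not exceeded by any axis-adjacent neighbour), sorted by
    chi2.
    """
    lambdas = tuple(lambda_range)
    ltbs = tuple(l_TB_pct_range)
    ltas = tuple(l_TA_pct_range)
    if not lambdas or not ltbs or not ltas:
        raise ValueError("empty grid")
    surface = np.full((len(lambdas), len(ltbs), len(ltas)), np.nan)
    n_skipped = 0
    for j, ltb in enumerate(ltbs):
        for k, lta in enumerate(ltas):
            try:
                ScoringThresholds.from_percent(lta, ltb, geom.m).validate_for(geom)
            except ValueError:
                n_skipped += len(lambdas)
                continue
            for i, lam in enumerate(lambdas):
                surface[i, j, k] = chi2_at_point(
                    lam, ltb, lta, data, geom, tail_tol=tail_tol, r_mode=r_mode
                ).chi2
    if np.all(np.isnan(surface)):
        raise ValueError("all grid points degenerate; nothing evaluated")
    flat_idx = np.nanargmin(surface)
    i, j, k = np.unravel_index(flat_idx, surface.shape)
    global_min = {
        "lambda": lambdas[i],
        "l_TB_pct": ltbs[j],
        "l_TA_pct": ltas[k],
        "chi2": float(surface[i, j, k]),
    }
    local = _local_minima(surface, (lambdas, ltbs, ltas))
    return GridSearchResult(
        lambdas=lambdas,
        l_TB_pcts=ltbs,
        l_TA_pcts=ltas,
        chi2_surface=surface,
        global_minimum=global_min,
        local_minima=tuple(local),
        n_skipped=n_skipped,
    )
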