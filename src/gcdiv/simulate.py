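"""Forward Monte-Carlo of GC seeding, expansion, sectioning and scoring.

Serves as the brute-force cross-check of the analytic section-classification
probabilities, and provides a synthetic stained-section renderer for
illustration and fixture generation.

Each replicate GC gets one section (mirroring the analytic one-section
assumption): founder number n (fixed, or Poisson conditioned on n >= 1 by
rejection), k ~ Binomial(n, p) type-B founders, deterministic expansion to
r = round(k*M/n) type-B cells, and a single hypergeometric draw of the
section's type-B count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    ChimeraMix,
    FractionTriple,
    ObservedSectionData,
    ScoringThresholds,
    SectionGeometry,
    SeedingModel,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "StainParams",
    "SectionImage",
    "simulate_sections",
    "generate_observed_dataset",
    "render_section",
]

SCORE_A, SCORE_B, SCORE_MIX = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    mix: ChimeraMix
    seeding: SeedingModel
    geom: SectionGeometry
    thresholds: ScoringThresholds
    n_gcs: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_gcs < 1:
            raise ValueError("n_gcs must be >= 1")
        self.thresholds.validate_for(self.geom)


@dataclass(frozen=True)
class SimulationResult:
    """Tallies and empirical fractions from one simulation run.

    ``fractions`` is directly comparable with the analytic model: plain
    empirical fractions in fixed-n mode, and conditional-on-seeded fractions
    rescaled by ``1 - exp(-lam)`` in Poisson mode (the analytic Poisson triple
    omits the n = 0 term without renormalizing).
    """

    config: SimulationConfig
    counts: dict[str, int]
    fractions: FractionTriple
    conditional_fractions: FractionTriple
    scores: np.ndarray = field(repr=False)  # per-GC category codes

    def to_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_gcs": self.config.n_gcs,
            "counts": dict(self.counts),
            "fractions": dict(zip(("A", "B", "Mix"), self.fractions.as_tuple())),
            "conditional_fractions": dict(
                zip(("A", "B", "Mix"), self.conditional_fractions.as_tuple())
            ),
        }


def simulate_sections(config: SimulationConfig) -> SimulationResult:
    """Simulate one section per GC for ``n_gcs`` replicate GCs."""
    rng = np.random.default_rng(config.seed)
    geom, mix, thr = config.geom, config.mix, config.thresholds
    n_gcs = config.n_gcs

    if config.seeding.mode == "fixed":
        n = np.full(n_gcs, config.seeding.n, dtype=np.int64)
        scale = 1.0
    else:
        lam = config.seeding.lam
        n = rng.poisson(lam, n_gcs)
        # condition on n >= 1 by rejection
        zero = n == 0
        while zero.any():
            n[zero] = rng.poisson(lam, int(zero.sum()))
            zero = n == 0
        scale = 1.0 - math.exp(-lam)

    k = rng.binomial(n, mix.p)
    r = np.floor(k * geom.M / n + 0.5).astype(np.int64)
    b_in_section = rng.hypergeometric(r, geom.M - r, geom.m)
    a_in_section = geom.m - b_in_section

    scores = np.full(n_gcs, SCORE_MIX, dtype=np.int8)
    scores[b_in_section <= thr.l_TB] = SCORE_A
    scores[a_in_section <= thr.l_TA] = SCORE_B  # disjoint: l_TA + l_TB < m

    n_A = int(np.sum(scores == SCORE_A))
    n_B = int(np.sum(scores == SCORE_B))
    n_mix = n_gcs - n_A - n_B
    cond = FractionTriple(n_A / n_gcs, n_B / n_gcs, n_mix / n_gcs)
    comparable = FractionTriple(
        scale * cond.f_A, scale * cond.f_B, scale * cond.f_Mix
    )
    return SimulationResult(
        config=config,
        counts={"A": n_A, "B": n_B, "Mix": n_mix, "total": n_gcs},
        fractions=comparable,
        conditional_fractions=cond,
        scores=scores,
    )


def generate_observed_dataset(config: SimulationConfig) -> ObservedSectionData:
    """Package a simulation run as observed percentages for the fitting module."""
    result = simulate_sections(config)
    c = result.conditional_fractions
    return ObservedSectionData.from_fractions(
        c.f_A, c.f_B, c.f_Mix, config.mix, n_sections=config.n_gcs
    )


# ---------------------------------------------------------------------------
# Synthetic stained-section rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainParams:
    """Per-cell stain intensity = base * lognormal(sigma), clipped to [0, 1]."""

    base: float = 0.75
    sigma: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.base <= 1:
            raise ValueError("stain base must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("stain sigma must be >= 0")


@dataclass(frozen=True)
class SectionImage:
    """A synthetic section: cells on a pointy-top hexagonal lattice.

    ``cell_type`` codes: 'A' and 'B' for B cells of each phenotype, 'T' for
    non-B cells.  Only type-A cells carry positive stain intensity (one-sided
    staining).  Lattice rows are offset by half a cell; ``x``/``y`` are the
    planar centre coordinates.
    """

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray
    intensity: np.ndarray
    total_cells: int
    n_b_cells: int
    n_type_A: int
    type_A_fraction: float
    seed: Optional[int]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "row": self.rows,
                "col": self.cols,
                "x": self.x,
                "y": self.y,
                "cell_type": self.cell_type,
                "intensity": self.intensity,
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(
                f"# total_cells={self.total_cells} n_b_cells={self.n_b_cells} "
                f"n_type_A={self.n_type_A} type_A_fraction={self.type_A_fraction} "
                f"seed={self.seed}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    def to_png(self, path, cell_px: int = 14) -> None:
        """Optional raster render (requires Pillow)."""
        from PIL import Image, ImageDraw

        pad = 1.0
        w = int((self.x.max() + 2 * pad) * cell_px)
        h = int((self.y.max() + 2 * pad) * cell_px)
        img = Image.new("RGB", (w, h), (10, 10, 10))
        draw = ImageDraw.Draw(img)
        radius = 0.48 * cell_px
        for xi, yi, inten in zip(self.x, self.y, self.intensity):
            cx = (xi + pad) * cell_px
            cy = (yi + pad) * cell_px
            green = int(255 * inten)
            color = (0, green, 0) if green > 0 else (35, 35, 35)
            draw.ellipse(
                (cx - radius, cy - radius, cx + radius, cy + radius), fill=color
            )
        img.save(path)


def _hex_lattice(total_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``total_cells`` (row, col) positions of a roughly square
    pointy-top hexagonal lattice filled row by row."""
    ncols = max(int(math.ceil(math.sqrt(total_cells))), 1)
    rows, cols = [], []
    r = 0
    while len(rows) < total_cells:
        for c in range(ncols):
            rows.append(r)
            cols.append(c)
            if len(rows) == total_cells:
                break
        r += 1
    return np.asarray(rows), np.asarray(cols)


def render_section(
    type_A_fraction: float,
    total_cells: int = 202,
    b_cell_fraction: float = 0.8,
    stain: StainParams = StainParams(),
    seed: Optional[int] = None,
) -> SectionImage:
    """Render a synthetic immunofluorescence-stained GC section.

    ``round(b_cell_fraction * total_cells)`` lattice positions hold randomly
    placed B cells (the rest are unstained non-B cells); an exact
    ``round(type_A_fraction * n_b)`` of the B cells are type A and receive
    stain intensity drawn from ``stain``.  Deterministic under ``seed``.
    """
    if not 0 <= type_A_fraction <= 1:
        raise ValueError("type_A_fraction must be in [0, 1]")
    if not 0 <= b_cell_fraction <= 1:
        raise ValueError("b_cell_fraction must be in [0, 1]")
    if total_cells < 1:
        raise ValueError("total_cells must be >= 1")

    rng = np.random.default_rng(seed)
    rows, cols = _hex_lattice(total_cells)
    x = cols + 0.5 * (rows % 2)
    y = rows * (math.sqrt(3.0) / 2.0)

    n_b = round(b_cell_fraction * total_cells)
    n_A = round(type_A_fraction * n_b)

    cell_type = np.full(total_cells, "T", dtype="U1")
    b_idx = rng.choice(total_cells, size=n_b, replace=False)
    a_idx = rng.choice(b_idx, size=n_A, replace=False)
    cell_type[b_idx] = "B"
    cell_type[a_idx] = "A"

    intensity = np.zeros(total_cells)
    noise = rng.lognormal(mean=0.0, sigma=stain.sigma, size=n_A)
    intensity[a_idx] = np.clip(stain.base * noise, 0.0, 1.0)

    return SectionImage(
        rows=rows,
        cols=cols,
        x=x,
        y=y,
        cell_type=cell_type,
        intensity=intensity,
        total_cells=total_cells,
        n_b_cells=n_b,
        n_type_A=n_A,
        type_A_fraction=type_A_fraction,
        seed=seed,
    )
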