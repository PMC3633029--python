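"""File readers and writers for observed-section data and abundance tables.

Dialect: UTF-8, tab-separated, header row required for tabular files; lines
starting with '#' are comments.  Section-classification values are accepted
either as percentages (summing to ~100) or as fractions (summing to ~1);
anything else is rejected as ambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from ..types import AbundanceSample, ChimeraMix, ObservedSectionData

__all__ = [
    "detect_percentages",
    "read_observed_data",
    "read_abundance_table",
    "write_json_report",
]


def detect_percentages(a: float, b: float, mix_val: float) -> tuple[float, float, float]:
    """Normalize (A, B, Mix) classification values to the percent scale.

    Sums near 100 are taken as percentages, near 1 as fractions; anything
    else is rejected rather than guessed.
    """
    total = a + b + mix_val
    if abs(total - 100.0) <= 0.5:
        return (a, b, mix_val)
    if abs(total - 1.0) <= 0.005:
        return (100.0 * a, 100.0 * b, 100.0 * mix_val)
    raise ValueError(
        f"ambiguous section-classification values summing to {total}; "
        "expected percentages (sum ~100) or fractions (sum ~1)"
    )


def read_observed_data(path: Union[str, Path]) -> ObservedSectionData:
    """Read a one-record observed-section file.

    Required columns: p, A, B, Mix (tab-separated, one data row).  An
    optional ``n_sections`` column is carried through.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"p", "A", "B", "Mix"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    if len(df) != 1:
        raise ValueError(f"{path}: expected exactly one data row, found {len(df)}")
    row = df.iloc[0]
    pct = detect_percentages(float(row["A"]), float(row["B"]), float(row["Mix"]))
    n_sections = int(row["n_sections"]) if "n_sections" in df.columns else None
    return ObservedSectionData(
        pct_A=pct[0],
        pct_B=pct[1],
        pct_Mix=pct[2],
        mix=ChimeraMix(p=float(row["p"])),
        n_sections=n_sections,
    )


def _read_bare_counts(path: Path) -> list[AbundanceSample]:
    tokens = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for tok in line.split():
            try:
                v = int(tok)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {tok!r}"
                ) from exc
            if v < 1:
                raise ValueError(f"{path}:{lineno}: count must be >= 1, got {v}")
            tokens.append(v)
    if not tokens:
        raise ValueError(f"{path}: no counts found")
    return [AbundanceSample.from_counts(tokens, name=path.stem)]


def read_abundance_table(path: Union[str, Path]) -> list[AbundanceSample]:
    """Read clone-abundance data into one sample per ``sample_id``.

    Two layouts are accepted: a headered TSV with columns ``clone_id`` and
    ``count`` (plus optional ``sample_id`` for multi-GC files), or a bare
    whitespace-separated vector of counts.
    """
    path = Path(path)
    first_data_line = ""
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            first_data_line = stripped
            break
    if "clone_id" not in first_data_line:
        return _read_bare_counts(path)

    df = pd.read_csv(path, sep="\t", comment="#")
    if "count" not in df.columns:
        raise ValueError(f"{path}: missing required column 'count'")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 1) | (counts != counts.round())]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"{path}: invalid counts (must be positive integers) at row(s) {rows}"
        )
    df = df.assign(count=counts.astype(int))
    samples = []
    if "sample_id" in df.columns:
        for sid, group in df.groupby("sample_id", sort=False):
            samples.append(
                AbundanceSample.from_counts(group["count"].tolist(), name=str(sid))
            )
    else:
        samples.append(AbundanceSample.from_counts(df["count"].tolist(), name=path.stem))
    return samples


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
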