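"""Per-species ecological descriptors: range, median, quartile-based CV.

For each species and environmental variable the descriptor set is the
realized environmental envelope over that species' accession sites: minimum,
maximum, median (Med), and a robust coefficient of variation

    CV = (Q / Med) * 100,   Q = (Q3 - Q1) / 2

(half the interquartile range relative to the median).  When the median is
zero — common for precipitation of the driest month in desert taxa — CV is
reported as 0 with a flag, mirroring how such cells are printed in
descriptor tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DescriptorCell", "quartiles", "descriptor_table"]


@dataclass(frozen=True)
class DescriptorCell:
    species: str
    variable: str
    n: int
    min: float
    max: float
    q1: float
    median: float
    q3: float
    cv: float
    zero_median: bool

    @property
    def q(self) -> float:
        return (self.q3 - self.q1) / 2.0


def quartiles(values: Sequence[float], method: str = "linear") -> tuple[float, float, float]:
    """(Q1, Med, Q3) of finite values.

    ``method`` is any numpy sample-quantile method; the default is linear
    interpolation at positions 0.25/0.5/0.75 * (n - 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(q1), float(med), float(q3)


def _cell(species: str, variable: str, vals: np.ndarray, method: str) -> DescriptorCell:
    q1, med, q3 = quartiles(vals, method=method)
    q = (q3 - q1) / 2.0
    zero = med == 0.0
    cv = 0.0 if zero else abs(q / med) * 100.0
    return DescriptorCell(
        species=species,
        variable=variable,
        n=int(vals.size),
        min=float(vals.min()),
        max=float(vals.max()),
        q1=q1,
        median=med,
        q3=q3,
        cv=cv,
        zero_median=zero,
    )


def descriptor_table(
    env: pd.DataFrame,
    species_of: Mapping[str, str],
    variables: Sequence[str] | None = None,
    method: str = "linear",
) -> list[DescriptorCell]:
    """One DescriptorCell per species x variable.

    Parameters
    ----------
    env
        Complete-case environmental matrix indexed by record id.
    species_of
        record id -> species name for every row of ``env``.
    variables
        Subset of columns to describe (default: all).
    method
        Quantile estimator, recorded in the output metadata by callers.
    """
    variables = list(variables) if variables is not None else list(env.columns)
    unknown = [i for i in env.index if i not in species_of]
    if unknown:
        raise KeyError(f"records with unknown species: {unknown[:5]}")
    species_col = pd.Series([species_of[i] for i in env.index], index=env.index)
    cells: list[DescriptorCell] = []
    for species in sorted(species_col.unique()):
        block = env.loc[species_col == species, variables].dropna()
        if block.empty:
            warnings.warn(f"species {species!r} has no usable rows; omitted", stacklevel=2)
            continue
        for var in variables:
            cells.append(_cell(species, var, block[var].to_numpy(), method))
    return cells


def descriptors_frame(cells: Sequence[DescriptorCell]) -> pd.DataFrame:
    """Long-format table (species, variable, n, min, max, median, cv, flag)."""
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "variable": c.variable,
                "n": c.n,
                "min": c.min,
                "max": c.max,
                "q1": c.q1,
                "median": c.median,
                "q3": c.q3,
                "cv": c.cv,
                "zero_median_flag": c.zero_median,
            }
            for c in cells
        ]
    )


def descriptors_wide(cells: Sequence[DescriptorCell]) -> pd.DataFrame:
    """Report-shaped wide table: one row per species, 'min-max / med (cv)' text."""
    frame = descriptors_frame(cells)
    frame["text"] = [
        f"{r['min']:g}-{r['max']:g} / {r['median']:g} ({r['cv']:.1f})"
        for _, r in frame.iterrows()
    ]
    return frame.pivot(index="species", columns="variable", values="text")
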