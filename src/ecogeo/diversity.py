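"""Edaphoclimatic diversity: class frequency tables and richness counts.

Each accession is assigned the class (Koeppen climate type, or FAO soil
unit) of the raster cell containing it; counts, within-row percentages, and
per-row richness (classes with nonzero count) are tabulated per species or
per phylogenetic group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .rasters import RasterGrid, extract_at_points
from .taxa import SpeciesGroupMap

__all__ = ["DiversityTable", "class_frequencies", "richness"]


@dataclass
class DiversityTable:
    """Class frequency table for one categorical layer.

    ``counts`` rows are species (or group labels), columns are class symbols;
    ``nodata`` holds per-row counts of accessions excluded for falling on
    nodata cells or outside the layer.
    """

    unit_kind: Literal["climate", "soil"]
    grouping: Literal["species", "group"]
    counts: pd.DataFrame
    nodata: pd.Series

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        pct = self.counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
        return pct

    @property
    def richness(self) -> pd.Series:
        return richness(self)

    def classes_observed(self) -> list[str]:
        """Class symbols observed at least once across all rows."""
        present = self.counts.sum(axis=0) > 0
        return list(self.counts.columns[present])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        stem = f"diversity_{self.unit_kind}_{self.grouping}"
        self.counts.to_csv(out / f"{stem}_counts.csv")
        self.percentages.to_csv(out / f"{stem}_pct.csv")


def class_frequencies(
    records: Sequence,
    grid: RasterGrid,
    class_dict: Mapping[int, str],
    unit_kind: Literal["climate", "soil"],
    grouping: Literal["species", "group"] = "species",
    group_map: SpeciesGroupMap | None = None,
) -> DiversityTable:
    """Tabulate categorical class membership per species or per group.

    Class codes absent from ``class_dict`` are tolerated and labeled
    ``UNKNOWN_<code>`` with a warning (synthetic layers may use subsets).
    """
    if grid.kind != "categorical":
        raise ValueError(f"grid {grid.name!r} is not categorical")
    if grouping == "group" and group_map is None:
        raise ValueError("grouping='group' requires a group_map")
    values = extract_at_points(grid, [(r.longitude, r.latitude) for r in records])
    rows: dict[str, dict[str, int]] = {}
    nodata: dict[str, int] = {}
    unknown_seen: set[int] = set()
    for rec, val in zip(records, values):
        key = (
            rec.species
            if grouping == "species"
            else group_map.label_of(rec.species)  # type: ignore[union-attr]
        )
        rows.setdefault(key, {})
        nodata.setdefault(key, 0)
        if val != val:  # NaN
            nodata[key] += 1
            continue
        code = int(val)
        symbol = class_dict.get(code)
        if symbol is None:
            symbol = f"UNKNOWN_{code}"
            if code not in unknown_seen:
                unknown_seen.add(code)
                warnings.warn(
                    f"class code {code} absent from dictionary; labeled {symbol}",
                    stacklevel=2,
                )
        rows[key][symbol] = rows[key].get(symbol, 0) + 1
    columns = list(dict.fromkeys(class_dict.values()))
    columns += sorted(
        {s for row in rows.values() for s in row if s.startswith("UNKNOWN_")}
    )
    counts = pd.DataFrame(
        [[rows[k].get(c, 0) for c in columns] for k in sorted(rows)],
        index=pd.Index(sorted(rows), name=grouping),
        columns=columns,
        dtype=int,
    )
    nodata_series = pd.Series(
        {k: nodata[k] for k in sorted(rows)}, name="nodata_excluded", dtype=int
    )
    return DiversityTable(
        unit_kind=unit_kind, grouping=grouping, counts=counts, nodata=nodata_series
    )


def richness(table: DiversityTable) -> pd.Series:
    """Per-row number of classes with nonzero count."""
    return (table.counts > 0).sum(axis=1).rename("richness")
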