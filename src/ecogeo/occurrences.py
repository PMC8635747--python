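"""Occurrence records: CSV reading, validation, and cleaning.

Curated occurrence databases for crop wild relatives are assembled from
herbarium and genebank passport data and are rife with exact duplicates,
coordinates truncated to a fraction of a degree, and records whose stated
location is implausible for the taxon.  Cleaning here applies four rules in a
fixed order — duplicates, coordinate precision, nodata location, altitude
envelope — and reports a full audit count for each.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .rasters import RasterGrid, extract_at_points

__all__ = [
    "OccurrenceRecord",
    "RowError",
    "CleaningReport",
    "read_occurrences",
    "write_occurrences",
    "clean_occurrences",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced accession of one species.

    ``longitude_text`` / ``latitude_text`` keep the raw CSV tokens so that the
    coordinate-precision rule can count decimal digits as written, which a
    parsed float cannot recover.
    """

    record_id: str
    species: str
    longitude: float
    latitude: float
    source: str = ""
    longitude_text: str = ""
    latitude_text: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class RowError:
    """A malformed CSV row, kept for reporting rather than silently dropped."""

    line_number: int
    message: str
    raw: dict


@dataclass
class CleaningReport:
    """Per-rule drop counts; ``kept + sum(dropped) == n_input`` always."""

    n_input: int = 0
    dropped_duplicate: int = 0
    dropped_precision: int = 0
    dropped_nodata: int = 0
    dropped_altitude: int = 0
    kept: int = 0

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_duplicate
            + self.dropped_precision
            + self.dropped_nodata
            + self.dropped_altitude
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped_duplicate": self.dropped_duplicate,
            "dropped_precision": self.dropped_precision,
            "dropped_nodata": self.dropped_nodata,
            "dropped_altitude": self.dropped_altitude,
            "kept": self.kept,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


DEFAULT_COLUMNS = {
    "species": "species",
    "longitude": "longitude",
    "latitude": "latitude",
    "record_id": "record_id",
    "source": "source",
}


def read_occurrences(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[list[OccurrenceRecord], list[RowError]]:
    """Read an occurrence CSV.

    Parameters
    ----------
    path
        UTF-8 CSV with a header row.
    columns
        Maps the logical fields (``species``, ``longitude``, ``latitude`` and
        optionally ``record_id``, ``source``) to the file's column names.
    delimiter
        CSV delimiter (``","`` default, ``";"`` for semicolon dialects).

    Returns
    -------
    (records, errors)
        Parsed records plus row-level errors with line numbers.  A missing
        required column is a hard error naming the column.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    records: list[OccurrenceRecord] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for logical in ("species", "longitude", "latitude"):
            if colmap[logical] not in header:
                raise ValueError(
                    f"required column {colmap[logical]!r} (for {logical}) "
                    f"not in header {header}"
                )
        has_id = colmap["record_id"] in header
        has_source = colmap["source"] in header
        for i, row in enumerate(reader, start=2):
            lon_text = (row.get(colmap["longitude"]) or "").strip()
            lat_text = (row.get(colmap["latitude"]) or "").strip()
            species = (row.get(colmap["species"]) or "").strip()
            try:
                lon = float(lon_text)
                lat = float(lat_text)
            except ValueError:
                errors.append(
                    RowError(i, f"unparseable coordinate ({lon_text!r}, {lat_text!r})", row)
                )
                continue
            rid = (row.get(colmap["record_id"]) or "").strip() if has_id else ""
            try:
                rec = OccurrenceRecord(
                    record_id=rid or f"row{i}",
                    species=species,
                    longitude=lon,
                    latitude=lat,
                    source=(row.get(colmap["source"]) or "").strip() if has_source else "",
                    longitude_text=lon_text,
                    latitude_text=lat_text,
                )
            except ValueError as exc:
                errors.append(RowError(i, str(exc), row))
                continue
            records.append(rec)
    return records, errors


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "species", "longitude", "latitude", "source"])
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.species,
                    r.longitude_text or repr(r.longitude),
                    r.latitude_text or repr(r.latitude),
                    r.source,
                ]
            )
    return path


def _decimal_digits(text: str, value: float) -> int:
    """Count decimal digits as written; falls back to repr of the float."""
    token = text if text else repr(value)
    token = token.strip()
    if "e" in token.lower():
        token = f"{value:.12f}".rstrip("0")
    if "." not in token:
        return 0
    return len(token.split(".", 1)[1])


def _coord_key(rec: OccurrenceRecord) -> tuple[str, str, str]:
    # string-normalized exact-duplicate key (species + coordinate pair)
    return (
        rec.species,
        (rec.longitude_text or repr(rec.longitude)).strip(),
        (rec.latitude_text or repr(rec.latitude)).strip(),
    )


def clean_occurrences(
    records: Sequence[OccurrenceRecord],
    altitude_grid: RasterGrid,
    altitude_ranges: Mapping[str, tuple[float, float]],
    min_decimals: int = 2,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Apply the four cleaning rules in fixed order and audit every drop.

    Order: exact duplicates (same species + identical string-normalized
    coordinate pair, first occurrence kept) -> coordinate precision (both
    coordinates need at least ``min_decimals`` written decimal digits) ->
    nodata location (altitude grid has no value at the point) -> altitude
    envelope (grid altitude outside the species range).

    The default ``min_decimals=2`` corresponds to roughly 1.1 km at the
    equator, on par with a 900 m environmental layer.  Output is sorted by
    species then record_id, so cleaning is idempotent and order-independent.
    """
    if min_decimals < 0:
        raise ValueError("min_decimals must be >= 0")
    present = {r.species for r in records}
    uncovered = sorted(present - set(altitude_ranges))
    if uncovered:
        raise ValueError(f"species missing from altitude_ranges: {uncovered}")

    report = CleaningReport(n_input=len(records))

    seen: set[tuple[str, str, str]] = set()
    stage: list[OccurrenceRecord] = []
    for rec in records:
        key = _coord_key(rec)
        if key in seen:
            report.dropped_duplicate += 1
        else:
            seen.add(key)
            stage.append(rec)

    precise: list[OccurrenceRecord] = []
    for rec in stage:
        lon_d = _decimal_digits(rec.longitude_text, rec.longitude)
        lat_d = _decimal_digits(rec.latitude_text, rec.latitude)
        if lon_d < min_decimals or lat_d < min_decimals:
            report.dropped_precision += 1
        else:
            precise.append(rec)

    altitudes = extract_at_points(
        altitude_grid, [(r.longitude, r.latitude) for r in precise]
    )
    kept: list[OccurrenceRecord] = []
    for rec, alt in zip(precise, altitudes):
        if alt != alt:  # NaN: nodata cell or outside extent
            report.dropped_nodata += 1
            continue
        lo, hi = altitude_ranges[rec.species]
        if alt < lo or alt > hi:
            report.dropped_altitude += 1
            continue
        kept.append(rec)

    kept.sort(key=lambda r: (r.species, r.record_id))
    report.kept = len(kept)
    assert report.kept + report.total_dropped == report.n_input
    return kept, report
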