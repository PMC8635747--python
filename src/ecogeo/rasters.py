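"""Georeferenced regular grids: I/O, point extraction, environmental matrix.

A :class:`RasterGrid` is a single-band grid in geographic coordinates
(WGS84 decimal degrees).  Cell (0, 0) is the northwest cell and rows increase
southward.  A point (lon, lat) falls in the cell whose half-open intervals
``[west, west + cell_size)`` (longitude) and ``(north - cell_size, north]``
(latitude) contain it; extraction is nearest-cell (no interpolation), so the
same rule serves continuous and categorical layers.

Supported on disk: ESRI ASCII grid (``.asc``) and single-band GeoTIFF
(``.tif``/``.tiff`` via tifffile, with ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "read_grid",
    "write_grid",
    "extract_at_points",
    "build_env_matrix",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A georeferenced regular grid, continuous or categorical.

    Parameters
    ----------
    name
        Variable code (``Bio12``, ``ET``, ``Alt``, ``BD``, ...).
    kind
        ``"continuous"`` or ``"categorical"`` (integer class codes).
    origin
        (west longitude, north latitude) of the outer corner of cell (0, 0).
    cell_size
        Cell edge in decimal degrees; must be positive.
    nodata
        Sentinel value marking missing cells.
    values
        Row-major ``(n_rows, n_cols)`` array; categorical grids hold integer
        class codes (or the nodata sentinel).
    """

    name: str
    kind: Literal["continuous", "categorical"]
    origin: tuple[float, float]
    cell_size: float
    nodata: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown grid kind: {self.kind!r}")
        if self.kind == "categorical":
            data = self.values[self.values != self.nodata]
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("categorical grid contains non-integer codes")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def west(self) -> float:
        return self.origin[0]

    @property
    def north(self) -> float:
        return self.origin[1]

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Return (row, col) of the cell containing the point, or None."""
        col = math.floor((lon - self.west) / self.cell_size)
        row = math.floor((self.north - lat) / self.cell_size)
        # north edge belongs to row 0; west edge to col 0
        if lat == self.north:
            row = 0
        if row < 0 or row >= self.n_rows or col < 0 or col >= self.n_cols:
            return None
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata


def _write_asc(grid: RasterGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.west!r}\n")
        fh.write(f"yllcorner {grid.south!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(v) for v in row.tolist()) + "\n")


def _read_asc(path: Path, name: str, kind: str) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"ASCII grid header missing {sorted(missing)} in {path}")
    values = np.array(rows, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"ASCII grid shape {values.shape} inconsistent with header "
            f"({n_rows}, {n_cols}) in {path}"
        )
    cell = header["cellsize"]
    north = header["yllcorner"] + n_rows * cell
    return RasterGrid(
        name=name,
        kind=kind,  # type: ignore[arg-type]
        origin=(header["xllcorner"], north),
        cell_size=cell,
        nodata=header.get("nodata_value", -9999.0),
        values=values,
    )


def _write_tif(grid: RasterGrid, path: Path) -> None:
    import tifffile

    payload = grid.values.astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.west, grid.north, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, payload, extratags=extratags)


def _read_tif(path: Path, name: str, kind: str) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"GeoTIFF {path} lacks georeferencing tags") from exc
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if values.ndim != 2:
        raise ValueError(f"expected single-band GeoTIFF, got shape {values.shape}")
    cell_x, cell_y = float(scale[0]), float(scale[1])
    if not math.isclose(cell_x, cell_y, rel_tol=1e-9):
        raise ValueError("non-square cells are not supported")
    west = float(tiepoint[3])
    north = float(tiepoint[4])
    return RasterGrid(
        name=name,
        kind=kind,  # type: ignore[arg-type]
        origin=(west, north),
        cell_size=cell_x,
        nodata=nodata,
        values=np.asarray(values, dtype=float),
    )


def write_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid to ``.asc`` or GeoTIFF, chosen by file extension.

    The ASCII dialect round-trips float64 values bit-exactly (``repr``
    formatting); the GeoTIFF payload is stored as float32.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_asc(grid, path)
    elif suffix in (".tif", ".tiff"):
        _write_tif(grid, path)
    else:
        raise ValueError(f"unknown raster format: {path.name!r} (use .asc or .tif)")
    return path


def read_grid(
    path: str | Path,
    name: str | None = None,
    kind: Literal["continuous", "categorical"] = "continuous",
) -> RasterGrid:
    """Read a ``.asc`` or GeoTIFF grid; ``name`` defaults to the file stem."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name if name is not None else path.stem
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_asc(path, name, kind)
    if suffix in (".tif", ".tiff"):
        return _read_tif(path, name, kind)
    raise ValueError(f"unknown raster format: {path.name!r} (use .asc or .tif)")


def extract_at_points(
    grid: RasterGrid, points: Iterable[tuple[float, float]]
) -> list[float]:
    """Sample the grid at (lon, lat) points; missing is returned as NaN.

    A point outside the extent or on a nodata cell yields NaN — missing is a
    value here, not an error.  Extraction is order-independent.
    """
    out: list[float] = []
    for lon, lat in points:
        idx = grid.cell_index(lon, lat)
        if idx is None:
            out.append(math.nan)
            continue
        v = grid.values[idx]
        out.append(math.nan if v == grid.nodata else float(v))
    return out


def build_env_matrix(
    records: Sequence, grids: Sequence[RasterGrid]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the accessions x variables environmental matrix.

    Returns ``(env, dropped)``: ``env`` is a DataFrame indexed by record id
    with one column per grid, complete cases only; ``dropped`` reports each
    removed row with the variables that were missing for it.  Column *g* of
    ``env`` equals ``extract_at_points(g, coords)`` restricted to kept rows.
    """
    names = [g.name for g in grids]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate grid names: {dupes}")
    ids = [r.record_id for r in records]
    coords = [(r.longitude, r.latitude) for r in records]
    columns = {g.name: extract_at_points(g, coords) for g in grids}
    env = pd.DataFrame(columns, index=pd.Index(ids, name="record_id"), dtype=float)
    missing_mask = env.isna()
    bad = missing_mask.any(axis=1)
    dropped = pd.DataFrame(
        {
            "record_id": env.index[bad],
            "missing_variables": [
                ",".join(env.columns[missing_mask.loc[i]]) for i in env.index[bad]
            ],
        }
    ).reset_index(drop=True)
    return env.loc[~bad], dropped
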