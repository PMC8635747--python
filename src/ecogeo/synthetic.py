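"""Synthetic study inputs with known ground truth.

Every pipeline stage is testable without licensed global rasters or curated
occurrence databases: this module fabricates (a) paired variable blocks with
planted canonical correlations, (b) a smooth raster landscape whose climate
and soil layers share a latent humidity field (planting a dominant
climate-soil canonical correlation), (c) species occurrences clustered in
distinct niches with optional planted cleaning defects, and (d) categorical
layers with exact class-count proportions.  Everything is a pure function of
(config, seed), and each generator records the truth it planted so
downstream tests check recovery, not plausibility.

The default study window mimics the western South American range of wild
tomatoes (Pacific coast and Andes) purely for coordinate realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .occurrences import OccurrenceRecord
from .rasters import RasterGrid
from .taxa import ALTITUDE_RANGES_M, SPECIES

__all__ = [
    "SyntheticConfig",
    "planted_cca_sample",
    "synthetic_landscape",
    "synthetic_occurrences",
    "categorical_layer",
]

#: per-layer construction: code -> (weight on humidity latent, weight on
#: thermal latent, offset, scale).  Residual white-noise weight is
#: sqrt(1 - bH^2 - bT^2) so each layer has unit variance before scaling.
LANDSCAPE_LAYERS: dict[str, tuple[float, float, float, float]] = {
    # climate block: humidity-driven moisture layers, thermally driven rest
    "ET": (0.90, 0.00, 800.0, 400.0),
    "Bio12": (0.92, 0.00, 1000.0, 700.0),
    "Bio14": (0.85, 0.00, 20.0, 15.0),
    "Bio1": (0.00, 0.90, 18.0, 6.0),
    "Bio2": (0.00, 0.60, 12.0, 3.0),
    "Bio3": (0.30, 0.60, 60.0, 15.0),
    "Bio7": (0.00, 0.75, 20.0, 6.0),
    # soil block: physico-chemical quality tracks humidity (wetter -> more
    # leached, acid, low-base soils), texture weakly coupled
    "BD": (-0.85, 0.00, 1.30, 0.20),
    "pH": (-0.80, 0.00, 6.5, 1.0),
    "BS": (-0.82, 0.00, 70.0, 20.0),
    "SA": (-0.40, 0.00, 50.0, 15.0),
    "SI": (0.35, 0.00, 30.0, 10.0),
    "CL": (0.30, 0.00, 20.0, 10.0),
    "CO": (0.50, 0.00, 2.0, 1.0),
    "CEC": (0.45, 0.00, 15.0, 5.0),
    "CaCO3": (-0.35, 0.00, 2.0, 1.5),
    "SOD": (-0.30, 0.00, 5.0, 3.0),
    "SAL": (-0.25, 0.00, 1.0, 0.8),
}

CLIMATE_LAYER_CODES = ("ET", "Alt", "Bio14", "Bio12", "Bio7", "Bio3", "Bio2", "Bio1")
SOIL_LAYER_CODES = (
    "SA", "SI", "CL", "BD", "pH", "CO", "CEC", "BS", "CaCO3", "SOD", "SAL"
)

ALT_MAX_M = 4500.0  # synthetic altitude gradient top (west 0 m -> east 4500 m)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic inputs.

    Defaults follow the study design they emulate: 16 taxa, 200 accessions
    per species, a ~13 x 13 degree Andean-coastal window on a 200 x 200
    grid, 30 km niche dispersion, and planted canonical correlations
    (0.8, 0.4, 0.2).
    """

    seed: int = 0
    n_per_species: int = 200
    species: tuple[str, ...] = SPECIES
    west: float = -81.0
    east: float = -68.0
    south: float = -13.0
    north: float = 0.0
    n_rows: int = 200
    n_cols: int = 200
    dispersion_km: float = 30.0
    rho: tuple[float, ...] = (0.8, 0.4, 0.2)
    n_duplicates: int = 0
    n_low_precision: int = 0
    n_out_of_altitude: int = 0
    n_off_grid: int = 0
    climate_proportions: tuple[float, ...] = (0.30, 0.25, 0.15, 0.10, 0.08, 0.07, 0.05)
    soil_proportions: tuple[float, ...] = (0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04)

    @property
    def cell_size(self) -> float:
        return (self.east - self.west) / self.n_cols

    def __post_init__(self) -> None:
        rho = tuple(self.rho)
        if any(not 0 <= r < 1 for r in rho):
            raise ValueError("planted correlations must lie in [0, 1)")
        if any(rho[i] < rho[i + 1] for i in range(len(rho) - 1)):
            raise ValueError("planted correlations must be descending")
        cell_h = (self.north - self.south) / self.n_rows
        if not np.isclose(cell_h, self.cell_size):
            raise ValueError("extent/shape must give square cells")


def _random_invertible(rng: np.random.Generator, d: int) -> np.ndarray:
    """Well-conditioned random invertible matrix: orthogonal x diagonal."""
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    return q @ np.diag(rng.uniform(0.5, 2.0, size=d))


def planted_cca_sample(
    n: int,
    p: int,
    q: int,
    rho: Sequence[float],
    seed: int = 0,
    identity_mixing: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw paired blocks whose population canonical correlations equal rho.

    Construction: shared standard-normal latents z_k give u_k = z_k and
    v_k = rho_k z_k + sqrt(1 - rho_k^2) e_k, padded with independent normals
    to p and q columns, then mixed within each block by a fixed random
    invertible matrix — canonical correlations are invariant to within-block
    invertible mixing, so the population truth is exactly rho.
    """
    rho = np.asarray(rho, dtype=float)
    s = len(rho)
    if s > min(p, q):
        raise ValueError(f"len(rho)={s} exceeds min(p, q)={min(p, q)}")
    if np.any(np.diff(rho) > 0):
        raise ValueError("rho must be non-ascending")
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("rho entries must lie in [0, 1)")
    if n <= p + q:
        raise ValueError(f"need n > p + q; have n={n}")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, s))
    e = rng.normal(size=(n, s))
    u = z
    v = rho * z + np.sqrt(1.0 - rho**2) * e
    X0 = np.hstack([u, rng.normal(size=(n, p - s))])
    Y0 = np.hstack([v, rng.normal(size=(n, q - s))])
    if identity_mixing:
        mx, my = np.eye(p), np.eye(q)
    else:
        mx = _random_invertible(rng, p)
        my = _random_invertible(rng, q)
    truth = {"rho": rho.tolist(), "mix_x": mx.tolist(), "mix_y": my.tolist()}
    return X0 @ mx, Y0 @ my, truth


def _standardized_field(
    lon: np.ndarray, lat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Smooth unit-variance field: linear gradient plus seeded sinusoids."""
    xn = (lon - lon.min()) / (lon.max() - lon.min())
    yn = (lat - lat.min()) / (lat.max() - lat.min())
    a1, a2 = rng.uniform(-1.5, 1.5, size=2)
    f1, f2 = rng.uniform(1.0, 3.0, size=2)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    f = a1 * xn + a2 * yn + np.sin(2 * np.pi * f1 * xn + p1) + np.cos(
        2 * np.pi * f2 * yn + p2
    )
    return (f - f.mean()) / f.std()


def _cell_centers(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    cell = config.cell_size
    lons = config.west + (np.arange(config.n_cols) + 0.5) * cell
    lats = config.north - (np.arange(config.n_rows) + 0.5) * cell
    return np.meshgrid(lons, lats)


def altitude_at(config: SyntheticConfig, lon: np.ndarray | float) -> np.ndarray | float:
    """Closed-form synthetic altitude: 0 m at the west edge, rising east."""
    return ALT_MAX_M * (np.asarray(lon) - config.west) / (config.east - config.west)


def altitude_cell_value(config: SyntheticConfig, lon: float) -> float:
    """Altitude the Alt raster reports for a point: its cell-center value."""
    col = int(np.floor((lon - config.west) / config.cell_size))
    col = min(max(col, 0), config.n_cols - 1)
    center = config.west + (col + 0.5) * config.cell_size
    return float(altitude_at(config, center))


def synthetic_landscape(
    config: SyntheticConfig, noise_sd: float = 1.0
) -> tuple[list[RasterGrid], dict]:
    """Generate the continuous environmental layers plus a truth record.

    Climate and soil layers are affine functions of a shared latent humidity
    field (plus an independent thermal field and per-cell white noise), so a
    dominant climate-soil canonical correlation is planted by construction.
    ``noise_sd`` rescales the white-noise component (0 gives each layer as an
    exact closed-form field).  The truth record stores per-layer
    coefficients and the realized leading canonical correlation over all
    grid cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lon, lat = _cell_centers(config)
    humidity = _standardized_field(lon, lat, rng)
    thermal = _standardized_field(lon, lat, rng)
    grids: list[RasterGrid] = []
    truth: dict = {
        "layers": {},
        "noise_sd": noise_sd,
        "fields": {"humidity": humidity.tolist()},
    }
    for code, (b_h, b_t, offset, scale) in LANDSCAPE_LAYERS.items():
        resid = np.sqrt(max(1.0 - b_h**2 - b_t**2, 0.0)) * noise_sd
        eps = rng.normal(size=lon.shape)
        values = offset + scale * (b_h * humidity + b_t * thermal + resid * eps)
        grids.append(
            RasterGrid(
                name=code,
                kind="continuous",
                origin=(config.west, config.north),
                cell_size=config.cell_size,
                nodata=-9999.0,
                values=values,
            )
        )
        truth["layers"][code] = {
            "b_humidity": b_h, "b_thermal": b_t, "offset": offset,
            "scale": scale, "noise": resid,
        }
    alt = np.asarray(altitude_at(config, lon), dtype=float)
    grids.append(
        RasterGrid(
            name="Alt",
            kind="continuous",
            origin=(config.west, config.north),
            cell_size=config.cell_size,
            nodata=-9999.0,
            values=alt,
        )
    )
    truth["layers"]["Alt"] = {
        "b_humidity": 0.0, "b_thermal": 0.0, "offset": 0.0,
        "scale": ALT_MAX_M, "noise": 0.0,
    }
    truth["planted_leading_r"] = _cell_population_leading_r(grids)
    return grids, truth


def _cell_population_leading_r(grids: Sequence[RasterGrid]) -> float:
    """Leading canonical correlation over all grid cells (the planted truth)."""
    import pandas as pd

    from .cca import fit_cca, standardize

    by_name = {g.name: g for g in grids}
    x_cols = {c: by_name[c].values.ravel() for c in CLIMATE_LAYER_CODES if c in by_name}
    y_cols = {c: by_name[c].values.ravel() for c in SOIL_LAYER_CODES if c in by_name}
    X = standardize(pd.DataFrame(x_cols))
    Y = standardize(pd.DataFrame(y_cols))
    try:
        return float(fit_cca(X, Y).correlations[0])
    except np.linalg.LinAlgError:
        # zero-noise layers are perfectly collinear within a block
        return float(fit_cca(X, Y, ridge=1e-8).correlations[0])


def categorical_layer(
    config: SyntheticConfig,
    proportions: Sequence[float],
    name: str = "classes",
    codes: Sequence[int] | None = None,
    seed_tag: int = 7,
) -> tuple[RasterGrid, dict]:
    """Categorical grid with *exact* cell-count class proportions.

    Cells of a smooth seeded field are ranked and split at the cumulative
    proportion boundaries, so class k occupies exactly
    ``round(cum_k * n_cells) - round(cum_{k-1} * n_cells)`` cells.
    """
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if np.any(props < 0):
        raise ValueError("proportions must be nonnegative")
    codes = list(codes) if codes is not None else list(range(1, len(props) + 1))
    if len(codes) != len(props):
        raise ValueError("codes and proportions must align")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_tag]))
    lon, lat = _cell_centers(config)
    base = _standardized_field(lon, lat, rng)
    flat = base.ravel()
    order = np.argsort(flat, kind="stable")
    n_cells = flat.size
    bounds = np.round(np.cumsum(props) * n_cells).astype(int)
    out = np.empty(n_cells, dtype=float)
    start = 0
    for code, stop in zip(codes, bounds):
        out[order[start:stop]] = code
        start = stop
    out[order[start:]] = codes[-1]  # rounding remainder
    grid = RasterGrid(
        name=name,
        kind="categorical",
        origin=(config.west, config.north),
        cell_size=config.cell_size,
        nodata=-9999.0,
        values=out.reshape(base.shape),
    )
    counts = {int(c): int((out == c).sum()) for c in codes}
    truth = {"proportions": props.tolist(), "codes": codes, "cell_counts": counts}
    return grid, truth


def _niche_center(
    config: SyntheticConfig, species: str, idx: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Species niche center: longitude set by the altitude gradient so the
    species' elevational envelope is satisfied at the center; latitude spaced
    along the window."""
    lo, hi = ALTITUDE_RANGES_M.get(species, (0.0, ALT_MAX_M))
    target_alt = min((lo + hi) / 2.0, ALT_MAX_M * 0.95)
    lon = config.west + (target_alt / ALT_MAX_M) * (config.east - config.west)
    span = config.north - config.south
    lat = config.south + (idx + 0.5) / len(config.species) * span
    lat += rng.uniform(-0.02, 0.02) * span
    return lon, lat


def synthetic_occurrences(
    config: SyntheticConfig,
) -> tuple[list[OccurrenceRecord], dict]:
    """Clustered species occurrences plus a planted-defect ledger.

    Clean points are rejection-sampled Gaussians (dispersion in km,
    converted to degrees with the local-latitude cosine) around each
    species' niche center, constrained to the window and to the species'
    altitude envelope under the synthetic gradient — so they survive
    cleaning.  Planted defects (exact duplicates, low-precision coordinates,
    out-of-envelope altitudes, off-grid locations) are appended and counted
    in the ledger for round-trip cleaning tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    records: list[OccurrenceRecord] = []
    seen: set[tuple[str, str, str]] = set()
    counter = 0

    def fmt(v: float) -> str:
        return f"{v:.6f}"

    def add(
        species: str, lon: float, lat: float, tag: str, force: bool = False
    ) -> OccurrenceRecord | None:
        nonlocal counter
        lon_t, lat_t = fmt(lon), fmt(lat)
        key = (species, lon_t, lat_t)
        if key in seen and not force:
            return None
        seen.add(key)
        counter += 1
        rec = OccurrenceRecord(
            record_id=f"SYN{counter:06d}",
            species=species,
            longitude=float(lon_t),
            latitude=float(lat_t),
            source=tag,
            longitude_text=lon_t,
            latitude_text=lat_t,
        )
        records.append(rec)
        return rec

    clean: list[OccurrenceRecord] = []
    for idx, species in enumerate(config.species):
        lon_c, lat_c = _niche_center(config, species, idx, rng)
        lo, hi = ALTITUDE_RANGES_M.get(species, (0.0, ALT_MAX_M))
        made = 0
        while made < config.n_per_species:
            dx, dy = rng.normal(scale=config.dispersion_km, size=2)
            lat = lat_c + dy / 111.32
            lon = lon_c + dx / (111.32 * np.cos(np.radians(lat_c)))
            if not (config.west <= lon < config.east and config.south < lat <= config.north):
                continue
            alt = altitude_cell_value(config, float(f"{lon:.6f}"))
            if not lo <= alt <= hi:
                continue
            # dispersion 0 degenerates to one repeated coordinate; force it
            rec = add(species, lon, lat, "clean", force=config.dispersion_km == 0)
            if rec is not None:
                clean.append(rec)
                made += 1

    sp_names = list(config.species)
    for _ in range(config.n_duplicates):
        src = clean[rng.integers(len(clean))]
        counter += 1
        records.append(
            OccurrenceRecord(
                record_id=f"SYN{counter:06d}",
                species=src.species,
                longitude=src.longitude,
                latitude=src.latitude,
                source="planted_duplicate",
                longitude_text=src.longitude_text,
                latitude_text=src.latitude_text,
            )
        )

    made = 0
    while made < config.n_low_precision:
        species = sp_names[rng.integers(len(sp_names))]
        lon = round(rng.uniform(config.west, config.east), 1)
        lat = round(rng.uniform(config.south, config.north), 1)
        lon_t, lat_t = f"{lon:.1f}", f"{lat:.1f}"
        key = (species, lon_t, lat_t)
        if key in seen:
            continue
        seen.add(key)
        counter += 1
        records.append(
            OccurrenceRecord(
                record_id=f"SYN{counter:06d}",
                species=species,
                longitude=lon,
                latitude=lat,
                source="planted_low_precision",
                longitude_text=lon_t,
                latitude_text=lat_t,
            )
        )
        made += 1

    made = 0
    while made < config.n_out_of_altitude:
        species = sp_names[rng.integers(len(sp_names))]
        hi = ALTITUDE_RANGES_M.get(species, (0.0, ALT_MAX_M))[1]
        lon_floor = config.west + (hi / ALT_MAX_M) * (config.east - config.west)
        margin = 0.02 * (config.east - config.west)
        if lon_floor + margin >= config.east:
            continue  # species envelope reaches the gradient top
        lon = rng.uniform(lon_floor + margin, config.east - 1e-6)
        lat = rng.uniform(config.south + 1e-6, config.north)
        if add(species, lon, lat, "planted_out_of_altitude") is not None:
            made += 1

    made = 0
    while made < config.n_off_grid:
        species = sp_names[rng.integers(len(sp_names))]
        lon = rng.uniform(config.east + 0.5, config.east + 3.0)
        lat = rng.uniform(config.south, config.north)
        if add(species, lon, lat, "planted_off_grid") is not None:
            made += 1

    ledger = {
        "n_clean": len(clean),
        "n_duplicates": config.n_duplicates,
        "n_low_precision": config.n_low_precision,
        "n_out_of_altitude": config.n_out_of_altitude,
        "n_off_grid": config.n_off_grid,
        "n_total": len(records),
        "species": sp_names,
        "n_per_species": config.n_per_species,
    }
    return records, ledger


def write_truth(truth: dict, path: str | Path) -> None:
    slim = {k: v for k, v in truth.items() if k != "fields"}
    Path(path).write_text(json.dumps(slim, indent=2) + "\n")
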