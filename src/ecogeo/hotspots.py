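"""Hot spot detection: 1-km density binning and the Getis-Ord Gi* statistic.

Accession points are projected to a local azimuthal-equidistant plane
anchored at their centroid, snapped to a fixed square grid (1 km by
default), and counted per occupied bin.  For each bin i the Gi* z-score
measures whether values within the band-distance neighborhood of i — the bin
itself included (w_ii = 1) — are higher (hot spot) or lower (cold spot) than
expected under spatial randomness:

    z_i = [ sum_j w_ij x_j - Xbar * S1_i ]
          / [ S * sqrt( (n * S2_i - S1_i^2) / (n - 1) ) ]

with Xbar and S the global mean and (population) standard deviation of the
bin values, S1_i = sum_j w_ij, S2_i = sum_j w_ij^2, over the full set of
occupied bins.  Classes follow the usual two-sided thresholds +-1.65 / 1.96
/ 2.58 (90 / 95 / 99%).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "HotspotCell",
    "SpatialWeights",
    "bin_points",
    "band_weights",
    "gi_star",
    "classify_spots",
    "hotspot_analysis",
]

EARTH_RADIUS_KM = 6371.0088

Z_THRESHOLDS = {"90": 1.65, "95": 1.96, "99": 2.58}


def aeqd_forward(
    lons: np.ndarray, lats: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical azimuthal-equidistant projection to km, anchored at (lon0, lat0)."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlam = lam - lam0
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def aeqd_inverse(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`aeqd_forward`; returns (lons, lats) in degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            c > 0,
            np.arcsin(cos_c * math.sin(phi0) + y * sin_c * math.cos(phi0) / np.where(c > 0, c, 1.0)),
            phi0,
        )
        lam = lam0 + np.where(
            c > 0,
            np.arctan2(
                x * sin_c,
                c * math.cos(phi0) * cos_c - y * math.sin(phi0) * sin_c,
            ),
            0.0,
        )
    return np.degrees(lam), np.degrees(phi)


@dataclass(frozen=True)
class HotspotCell:
    """A density bin with its aggregated value and Gi* result."""

    lon: float
    lat: float
    x_km: float
    y_km: float
    value: float
    z: float = math.nan
    p_value: float = math.nan
    label: str = "unclassified"


@dataclass
class SpatialWeights:
    """Binary band-distance neighbor structure; every bin is its own neighbor."""

    band_km: float
    neighbors: list[np.ndarray]  # per-bin indices, self included

    @property
    def n(self) -> int:
        return len(self.neighbors)


@dataclass
class BinnedPoints:
    """Occupied bins of the local-plane density grid."""

    cells: list[HotspotCell]
    bin_km: float
    anchor: tuple[float, float]  # (lon0, lat0) of the projection

    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.cells], dtype=float)

    def coords_km(self) -> np.ndarray:
        return np.array([(c.x_km, c.y_km) for c in self.cells], dtype=float)


def bin_points(
    points: Sequence[tuple[float, float]],
    bin_km: float = 1.0,
    species: Sequence[str] | None = None,
    aggregate: Literal["count", "richness"] = "count",
) -> BinnedPoints:
    """Snap points to a ``bin_km`` square grid in a local equidistant plane.

    The aggregated bin value is the accession count by default, or the number
    of distinct species (``aggregate="richness"``) when ``species`` labels are
    given.  Deterministic: independent of point order.
    """
    if bin_km <= 0:
        raise ValueError("bin_km must be positive")
    if aggregate == "richness" and species is None:
        raise ValueError("aggregate='richness' requires species labels")
    if not points:
        return BinnedPoints(cells=[], bin_km=bin_km, anchor=(0.0, 0.0))
    lons = np.array([p[0] for p in points], dtype=float)
    lats = np.array([p[1] for p in points], dtype=float)
    lon0, lat0 = float(lons.mean()), float(lats.mean())
    x, y = aeqd_forward(lons, lats, lon0, lat0)
    ix = np.floor(x / bin_km).astype(int)
    iy = np.floor(y / bin_km).astype(int)
    agg: dict[tuple[int, int], set | int] = {}
    for j in range(len(points)):
        key = (int(ix[j]), int(iy[j]))
        if aggregate == "count":
            agg[key] = agg.get(key, 0) + 1  # type: ignore[operator]
        else:
            agg.setdefault(key, set()).add(species[j])  # type: ignore[union-attr, index]
    cells: list[HotspotCell] = []
    for key in sorted(agg):
        cx = (key[0] + 0.5) * bin_km
        cy = (key[1] + 0.5) * bin_km
        lon, lat = aeqd_inverse(np.array([cx]), np.array([cy]), lon0, lat0)
        value = agg[key] if aggregate == "count" else len(agg[key])  # type: ignore[arg-type]
        cells.append(
            HotspotCell(lon=float(lon[0]), lat=float(lat[0]), x_km=cx, y_km=cy, value=float(value))
        )
    return BinnedPoints(cells=cells, bin_km=bin_km, anchor=(lon0, lat0))


def band_weights(binned: BinnedPoints, band_km: float = 50.0) -> SpatialWeights:
    """Binary weights: w_ij = 1 iff planar distance(i, j) <= band_km (self included)."""
    coords = binned.coords_km()
    tree = cKDTree(coords)
    neighbors = [
        np.array(sorted(idx), dtype=int)
        for idx in tree.query_ball_point(coords, r=band_km)
    ]
    return SpatialWeights(band_km=band_km, neighbors=neighbors)


def gi_star(binned: BinnedPoints, weights: SpatialWeights) -> list[HotspotCell]:
    """Getis-Ord Gi* z-score and normal p-value for every occupied bin.

    With zero global variance every z is defined as 0.  Bins whose
    neighborhood covers the whole study set get z = 0 (the variance term
    vanishes).
    """
    x = binned.values()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 bins")
    if weights.n != n:
        raise ValueError("weights do not cover all bins")
    xbar = x.mean()
    s = math.sqrt((x**2).mean() - xbar**2)  # population sd
    out: list[HotspotCell] = []
    for i, cell in enumerate(binned.cells):
        idx = weights.neighbors[i]
        s1 = float(len(idx))  # binary weights: S1 = S2 = neighbor count
        s2 = s1
        num = float(x[idx].sum()) - xbar * s1
        inner = (n * s2 - s1**2) / (n - 1)
        denom = s * math.sqrt(inner) if inner > 0 else 0.0
        z = num / denom if denom > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            HotspotCell(
                lon=cell.lon, lat=cell.lat, x_km=cell.x_km, y_km=cell.y_km,
                value=cell.value, z=z, p_value=p,
            )
        )
    return out


def classify_spots(cells: Sequence[HotspotCell]) -> list[HotspotCell]:
    """Attach significance class labels from the z thresholds."""
    out = []
    for c in cells:
        z = c.z
        if z >= Z_THRESHOLDS["99"]:
            label = "hot99"
        elif z >= Z_THRESHOLDS["95"]:
            label = "hot95"
        elif z >= Z_THRESHOLDS["90"]:
            label = "hot90"
        elif z <= -Z_THRESHOLDS["99"]:
            label = "cold99"
        elif z <= -Z_THRESHOLDS["95"]:
            label = "cold95"
        elif z <= -Z_THRESHOLDS["90"]:
            label = "cold90"
        else:
            label = "not_significant"
        out.append(
            HotspotCell(
                lon=c.lon, lat=c.lat, x_km=c.x_km, y_km=c.y_km,
                value=c.value, z=c.z, p_value=c.p_value, label=label,
            )
        )
    return out


def hotspot_analysis(
    points: Sequence[tuple[float, float]],
    bin_km: float = 1.0,
    band_km: float = 50.0,
    species: Sequence[str] | None = None,
    aggregate: Literal["count", "richness"] = "count",
) -> list[HotspotCell]:
    """bin -> weight -> Gi* -> classify, in one call."""
    binned = bin_points(points, bin_km=bin_km, species=species, aggregate=aggregate)
    if len(binned.cells) < 2:
        return classify_spots(
            [
                HotspotCell(
                    lon=c.lon, lat=c.lat, x_km=c.x_km, y_km=c.y_km,
                    value=c.value, z=0.0, p_value=1.0,
                )
                for c in binned.cells
            ]
        )
    weights = band_weights(binned, band_km=band_km)
    return classify_spots(gi_star(binned, weights))


def cells_frame(cells: Sequence[HotspotCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lon": c.lon, "lat": c.lat, "x_km": c.x_km, "y_km": c.y_km,
                "value": c.value, "z": c.z, "p_value": c.p_value, "class": c.label,
            }
            for c in cells
        ]
    )


def cells_geojson(cells: Sequence[HotspotCell], path: str | Path, **metadata) -> None:
    """Write classified bins as a GeoJSON FeatureCollection of points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.lon, c.lat]},
            "properties": {
                "value": c.value, "z": c.z, "p_value": c.p_value, "class": c.label,
            },
        }
        for c in cells
    ]
    doc = {"type": "FeatureCollection", "metadata": metadata, "features": features}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
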