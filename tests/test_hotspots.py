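"""Density binning, the Gi* statistic vs a brute-force oracle, and classes."""

import math

import numpy as np
import pytest
from scipy import stats

from ecogeo.hotspots import (
    BinnedPoints,
    HotspotCell,
    SpatialWeights,
    aeqd_forward,
    aeqd_inverse,
    band_weights,
    bin_points,
    classify_spots,
    gi_star,
    hotspot_analysis,
)


def brute_force_gi(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of the Gi* z formula."""
    n = len(x)
    xbar = x.mean()
    s = math.sqrt((x**2).sum() / n - xbar**2)
    out = np.empty(n)
    for i in range(n):
        s1 = w[i].sum()
        s2 = (w[i] ** 2).sum()
        num = (w[i] * x).sum() - xbar * s1
        inner = (n * s2 - s1**2) / (n - 1)
        denom = s * math.sqrt(inner) if inner > 0 else 0.0
        out[i] = num / denom if denom > 0 else 0.0
    return out


def _binned_from_values(coords_km: np.ndarray, values: np.ndarray) -> BinnedPoints:
    cells = [
        HotspotCell(lon=0.0, lat=0.0, x_km=float(cx), y_km=float(cy), value=float(v))
        for (cx, cy), v in zip(coords_km, values)
    ]
    return BinnedPoints(cells=cells, bin_km=1.0, anchor=(0.0, 0.0))


class TestProjection:
    def test_round_trip(self, rng):
        lons = rng.uniform(-80, -70, size=200)
        lats = rng.uniform(-15, 0, size=200)
        x, y = aeqd_forward(lons, lats, -75.0, -7.5)
        back_lon, back_lat = aeqd_inverse(x, y, -75.0, -7.5)
        assert np.allclose(back_lon, lons, atol=1e-9)
        assert np.allclose(back_lat, lats, atol=1e-9)

    def test_distance_preserved_from_anchor(self):
        # equidistant property: planar radius equals great-circle distance
        x, y = aeqd_forward(np.array([-74.0]), np.array([-8.0]), -75.0, -7.5)
        planar = math.hypot(x[0], y[0])
        great_circle = 6371.0088 * math.acos(
            math.sin(math.radians(-7.5)) * math.sin(math.radians(-8.0))
            + math.cos(math.radians(-7.5))
            * math.cos(math.radians(-8.0))
            * math.cos(math.radians(1.0))
        )
        assert planar == pytest.approx(great_circle, rel=1e-9)


class TestBinning:
    def test_identical_points_share_a_bin(self):
        binned = bin_points([(-75.0, -10.0), (-75.0, -10.0)])
        assert len(binned.cells) == 1
        assert binned.cells[0].value == 2

    def test_distant_points_get_distinct_bins(self):
        binned = bin_points([(-75.0, -10.0), (-75.0, -9.0)])  # ~111 km apart
        assert len(binned.cells) == 2
        assert [c.value for c in binned.cells] == [1.0, 1.0]

    def test_counts_conserved_and_order_independent(self, rng):
        pts = [
            (float(-75 + rng.normal(scale=0.05)), float(-10 + rng.normal(scale=0.05)))
            for _ in range(500)
        ]
        a = bin_points(pts)
        b = bin_points(pts[::-1])
        assert sum(c.value for c in a.cells) == 500
        assert [(c.x_km, c.y_km, c.value) for c in a.cells] == [
            (c.x_km, c.y_km, c.value) for c in b.cells
        ]

    def test_richness_aggregate(self):
        pts = [(-75.0, -10.0)] * 3
        species = ["a", "a", "b"]
        binned = bin_points(pts, species=species, aggregate="richness")
        assert binned.cells[0].value == 2

    def test_empty_input(self):
        assert bin_points([]).cells == []


class TestGiStar:
    def test_uniform_field_all_zero(self):
        coords = np.array([(float(i), 0.0) for i in range(10)])
        binned = _binned_from_values(coords, np.full(10, 4.0))
        weights = band_weights(binned, band_km=2.5)
        assert all(c.z == 0.0 for c in gi_star(binned, weights))

    def test_collinear_bins_match_hand_oracle(self):
        # 5 bins on a line, band covering one neighbor each side
        coords = np.array([(float(i), 0.0) for i in range(5)])
        values = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
        binned = _binned_from_values(coords, values)
        weights = band_weights(binned, band_km=1.0)
        w = np.array(
            [[1, 1, 0, 0, 0], [1, 1, 1, 0, 0], [0, 1, 1, 1, 0],
             [0, 0, 1, 1, 1], [0, 0, 0, 1, 1]],
            dtype=float,
        )
        expected = brute_force_gi(values, w)
        got = np.array([c.z for c in gi_star(binned, weights)])
        assert np.abs(got - expected).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fields_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        coords = rng.uniform(0, 40, size=(n, 2))
        values = rng.poisson(3.0, size=n).astype(float)
        if values.std() == 0:
            values[0] += 1
        binned = _binned_from_values(coords, values)
        weights = band_weights(binned, band_km=8.0)
        w = np.zeros((n, n))
        for i in range(n):
            d = np.hypot(*(coords - coords[i]).T)
            w[i, d <= 8.0] = 1.0
        expected = brute_force_gi(values, w)
        got = np.array([c.z for c in gi_star(binned, weights)])
        assert np.abs(got - expected).max() < 1e-10

    def test_every_bin_is_its_own_neighbor(self):
        coords = np.array([(0.0, 0.0), (100.0, 0.0)])
        binned = _binned_from_values(coords, np.array([1.0, 2.0]))
        weights = band_weights(binned, band_km=1.0)
        for i, nbrs in enumerate(weights.neighbors):
            assert i in nbrs

    def test_all_covering_weights_give_zero(self):
        coords = np.array([(float(i), 0.0) for i in range(6)])
        binned = _binned_from_values(coords, np.arange(6, dtype=float))
        weights = band_weights(binned, band_km=100.0)
        assert all(c.z == 0.0 for c in gi_star(binned, weights))

    def test_permutation_invariance(self, rng):
        n = 40
        coords = rng.uniform(0, 20, size=(n, 2))
        values = rng.poisson(2.0, size=n).astype(float) + 1
        perm = rng.permutation(n)
        a = gi_star(
            _binned_from_values(coords, values),
            band_weights(_binned_from_values(coords, values), 5.0),
        )
        b = gi_star(
            _binned_from_values(coords[perm], values[perm]),
            band_weights(_binned_from_values(coords[perm], values[perm]), 5.0),
        )
        za = np.array([c.z for c in a])
        zb = np.array([c.z for c in b])
        assert np.allclose(za[perm], zb, atol=1e-12)

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(33)
        # 50 sparse bins plus one bin holding a 100-point cluster
        sparse = [
            (float(lon), float(lat))
            for lon, lat in zip(
                rng.uniform(-76, -74, size=50), rng.uniform(-11, -9, size=50)
            )
        ]
        cluster = [(-75.0005, -10.0005)] * 100
        cells = hotspot_analysis(sparse + cluster, bin_km=1.0, band_km=30.0)
        hottest = max(cells, key=lambda c: c.value)
        assert hottest.value >= 100
        assert hottest.z > 2.58
        assert hottest.label == "hot99"


class TestClassification:
    @pytest.mark.parametrize(
        "z,label",
        [
            (3.0, "hot99"), (2.0, "hot95"), (1.7, "hot90"), (0.5, "not_significant"),
            (-1.7, "cold90"), (-2.0, "cold95"), (-3.0, "cold99"),
        ],
    )
    def test_threshold_labels(self, z, label):
        cell = HotspotCell(lon=0, lat=0, x_km=0, y_km=0, value=1.0, z=z, p_value=0.1)
        assert classify_spots([cell])[0].label == label

    def test_p_value_consistent_with_z(self):
        cell = HotspotCell(lon=0, lat=0, x_km=0, y_km=0, value=1.0)
        binned = _binned_from_values(
            np.array([(0.0, 0.0), (5.0, 0.0), (10.0, 0.0)]),
            np.array([5.0, 1.0, 0.0]),
        )
        out = gi_star(binned, band_weights(binned, 6.0))
        for c in out:
            assert c.p_value == pytest.approx(2 * stats.norm.sf(abs(c.z)))
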