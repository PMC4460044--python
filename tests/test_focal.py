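"""Raster-engine checks against independent brute-force oracles."""

import numpy as np
import pytest

from maxscale.focal import (ScaleSet, build_variable_stack, distance_to_feature,
                            edge_density, focal_statistic, max_patch_size,
                            terrain_slope_aspect, window_offsets)
from maxscale.grid import CategoricalRaster, Raster

from conftest import random_categorical, random_raster


# ---------------------------------------------------------------------------
# brute-force oracles: per-cell loops, no shared code with the implementation

def window_cells(r, c, shape, radius_m, cell_size):
    out = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            if ((i - r) ** 2 + (j - c) ** 2) * cell_size ** 2 <= radius_m ** 2 + 1e-9:
                out.append((i, j))
    return out


def brute_focal(raster, radius_m, stat, legend=None):
    vals, valid, cs = raster.values, raster.valid, raster.cell_size
    out = np.zeros(vals.shape)
    mask = np.zeros(vals.shape, dtype=bool)
    for r in range(vals.shape[0]):
        for c in range(vals.shape[1]):
            cells = [(i, j) for i, j in window_cells(r, c, vals.shape, radius_m, cs)
                     if valid[i, j]]
            if not cells:
                mask[r, c] = True
                continue
            w = [vals[i, j] for i, j in cells]
            if stat == "mean":
                out[r, c] = sum(w) / len(w)
            elif stat == "percent_cover":
                out[r, c] = 100.0 * sum(w) / len(w)
            elif stat == "majority":
                codes = sorted(legend)
                counts = {k: 0 for k in codes}
                for v in w:
                    counts[int(v)] += 1
                out[r, c] = max(codes, key=lambda k: (counts[k], -codes.index(k)))
            elif stat == "richness_proportion":
                out[r, c] = 100.0 * len(set(int(v) for v in w)) / len(legend)
    return out, mask


def brute_edge_density(raster, radius_m):
    vals, valid, cs = raster.values, raster.valid, raster.cell_size
    nr, nc = vals.shape
    wood = (vals != 0) & valid
    out = np.zeros(vals.shape)
    for r in range(nr):
        for c in range(nc):
            cells = [(i, j) for i, j in window_cells(r, c, vals.shape, radius_m, cs)
                     if valid[i, j]]
            if not cells:
                continue
            length_m = 0.0
            for i, j in cells:
                if not wood[i, j]:
                    continue
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nr and 0 <= nj < nc and valid[ni, nj] and not wood[ni, nj]:
                        length_m += cs
            out[r, c] = (length_m / 1000.0) / (len(cells) * (cs / 1000.0) ** 2)
    return out


def brute_max_patch(raster, radius_m):
    vals, valid, cs = raster.values, raster.valid, raster.cell_size
    nr, nc = vals.shape
    wood = (vals != 0) & valid
    # label components by flood fill (8-connectivity)
    labels = np.zeros(vals.shape, dtype=int)
    nid = 0
    for r in range(nr):
        for c in range(nc):
            if wood[r, c] and labels[r, c] == 0:
                nid += 1
                stack = [(r, c)]
                labels[r, c] = nid
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (0 <= ni < nr and 0 <= nj < nc and wood[ni, nj]
                                    and labels[ni, nj] == 0):
                                labels[ni, nj] = nid
                                stack.append((ni, nj))
    areas = {k: (labels == k).sum() * (cs / 1000.0) ** 2 for k in range(1, nid + 1)}
    out = np.zeros(vals.shape)
    for r in range(nr):
        for c in range(nc):
            in_win = {labels[i, j] for i, j in
                      window_cells(r, c, vals.shape, radius_m, cs) if labels[i, j]}
            out[r, c] = max((areas[k] for k in in_win), default=0.0)
    return out


# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stat,binary", [("mean", False), ("percent_cover", True)])
def test_focal_matches_bruteforce_continuous(rng, stat, binary):
    for trial in range(25):
        shape = (rng.integers(4, 16), rng.integers(4, 16))
        radius = float(rng.choice([100, 150, 250, 400]))
        r = random_raster(rng, shape, nodata_frac=0.2, binary=binary)
        got = focal_statistic(r, radius, stat)
        want, want_mask = brute_focal(r, radius, stat)
        assert np.array_equal(got.nodata_mask, want_mask)
        np.testing.assert_allclose(got.values[~want_mask], want[~want_mask],
                                   atol=1e-9)


@pytest.mark.parametrize("stat", ["majority", "richness_proportion"])
def test_focal_matches_bruteforce_categorical(rng, stat):
    for trial in range(25):
        shape = (rng.integers(4, 14), rng.integers(4, 14))
        radius = float(rng.choice([100, 200, 350]))
        r = random_categorical(rng, shape, n_classes=5, nodata_frac=0.15)
        got = focal_statistic(r, radius, stat)
        want, want_mask = brute_focal(r, radius, stat, legend=r.legend)
        np.testing.assert_allclose(got.values[~want_mask], want[~want_mask],
                                   atol=1e-9)


def test_focal_constant_and_bounds(rng):
    r = Raster(np.full((8, 8), 7.0), 100.0)
    out = focal_statistic(r, 300.0, "mean")
    np.testing.assert_allclose(out.values, 7.0)
    r2 = random_raster(rng, (10, 10))
    out2 = focal_statistic(r2, 300.0, "mean")
    assert out2.values.min() >= r2.values.min() - 1e-12
    assert out2.values.max() <= r2.values.max() + 1e-12


def test_percent_cover_single_centre_cell():
    vals = np.zeros((5, 5))
    vals[2, 2] = 1.0
    r = Raster(vals, 100.0)
    out = focal_statistic(r, 200.0, "percent_cover")
    n_window = len(window_cells(2, 2, (5, 5), 200.0, 100.0))
    assert n_window == 13  # radius 2 cells -> discrete disc of 13 cells
    np.testing.assert_allclose(out.values[2, 2], 100.0 / n_window)
    assert 0.0 <= out.values.min() and out.values.max() <= 100.0


def test_uniform_categorical_majority_and_richness():
    legend = {c: str(c) for c in range(1, 14)}
    r = CategoricalRaster(np.full((6, 6), 4.0), 100.0, legend=legend)
    assert np.all(focal_statistic(r, 250.0, "majority").values == 4.0)
    np.testing.assert_allclose(
        focal_statistic(r, 250.0, "richness_proportion").values, 100.0 / 13)


def test_window_membership_symmetric():
    offs = window_offsets(350.0, 100.0)
    s = {(dy, dx) for dy, dx in offs}
    assert all((-dy, -dx) in s for dy, dx in s)


def test_focal_errors():
    r = Raster(np.ones((5, 5)), 100.0)
    with pytest.raises(ValueError):
        focal_statistic(r, 50.0, "mean")  # radius below one cell
    with pytest.raises(ValueError):
        focal_statistic(Raster(np.full((5, 5), 2.0), 100.0), 200.0, "percent_cover")
    with pytest.raises(ValueError):
        focal_statistic(r, 200.0, "majority")  # needs categorical input


# ---------------------------------------------------------------------------
# terrain

def test_flat_dem_slope_zero_aspect_flat():
    slope, aspect = terrain_slope_aspect(Raster(np.full((6, 6), 50.0), 100.0))
    np.testing.assert_allclose(slope.values, 0.0)
    assert np.all(aspect.values == 0)  # "flat"


def test_plane_east_gradient_slope_and_west_aspect():
    x = np.arange(8) * 100.0
    dem = Raster(np.tile(0.1 * x, (6, 1)), 100.0)
    slope, aspect = terrain_slope_aspect(dem)
    np.testing.assert_allclose(slope.values, np.degrees(np.arctan(0.1)), atol=1e-9)
    assert np.all(aspect.values == 7)  # downslope faces west


def test_plane_north_gradient_aspect_south():
    y = np.arange(7)[::-1] * 100.0  # row 0 is north
    dem = Raster(np.tile(0.1 * y[:, None], (1, 6)), 100.0)
    _, aspect = terrain_slope_aspect(dem)
    assert np.all(aspect.values == 5)  # downslope faces south


def test_terrain_requires_3x3():
    with pytest.raises(ValueError):
        terrain_slope_aspect(Raster(np.ones((2, 5)), 100.0))


# ---------------------------------------------------------------------------
# distance

def test_distance_basics_and_lipschitz(rng):
    vals = np.zeros((9, 9))
    vals[4, 4] = 1.0
    d = distance_to_feature(Raster(vals, 100.0))
    assert d.values[4, 4] == 0.0
    assert d.values[4, 5] == pytest.approx(100.0)
    assert d.values[5, 5] == pytest.approx(100.0 * np.sqrt(2))
    r = random_raster(rng, (12, 12), binary=True)
    r.values[0, 0] = 1.0
    d = distance_to_feature(r).values
    # 1-Lipschitz: neighbouring cells differ by at most their centre distance
    assert np.all(np.abs(np.diff(d, axis=0)) <= 100.0 + 1e-9)
    assert np.all(np.abs(np.diff(d, axis=1)) <= 100.0 + 1e-9)


def test_distance_no_feature_errors():
    with pytest.raises(ValueError):
        distance_to_feature(Raster(np.zeros((4, 4)), 100.0))


# ---------------------------------------------------------------------------
# edge density and patches

def test_edge_density_trivial_cases():
    assert np.all(edge_density(Raster(np.ones((6, 6)), 100.0), 300.0).values == 0)
    assert np.all(edge_density(Raster(np.zeros((6, 6)), 100.0), 300.0).values == 0)


def test_edge_density_single_interior_cell_and_bruteforce(rng):
    vals = np.zeros((11, 11))
    vals[5, 5] = 1.0
    r = Raster(vals, 100.0)
    got = edge_density(r, 500.0)
    n_win = len(window_cells(5, 5, (11, 11), 500.0, 100.0))
    np.testing.assert_allclose(got.values[5, 5], (4 * 0.1) / (n_win * 0.01))
    for trial in range(10):
        r = random_raster(rng, (10, 10), binary=True, nodata_frac=0.1)
        got = edge_density(r, 300.0)
        np.testing.assert_allclose(got.values[~got.nodata_mask],
                                   brute_edge_density(r, 300.0)[~got.nodata_mask],
                                   atol=1e-9)


def test_max_patch_trivial_and_bruteforce(rng):
    assert np.all(max_patch_size(Raster(np.zeros((6, 6)), 100.0), 300.0).values == 0)
    full = max_patch_size(Raster(np.ones((10, 10)), 100.0), 300.0)
    np.testing.assert_allclose(full.values, 1.0)  # 100 cells x 0.01 km^2
    for trial in range(10):
        r = random_raster(rng, (12, 12), binary=True)
        got = max_patch_size(r, 400.0)
        np.testing.assert_allclose(got.values, brute_max_patch(r, 400.0), atol=1e-9)


def test_max_patch_two_patches_window_intersection():
    vals = np.zeros((9, 20))
    vals[4, 1:4] = 1.0    # 3-cell patch
    vals[4, 14:19] = 1.0  # 5-cell patch
    got = max_patch_size(Raster(vals, 100.0), 200.0)
    assert got.values[4, 2] == pytest.approx(0.03)
    assert got.values[4, 16] == pytest.approx(0.05)
    np.testing.assert_allclose(got.values, brute_max_patch(Raster(vals, 100.0), 200.0))


def test_max_patch_monotone_in_radius(rng):
    r = random_raster(rng, (14, 14), binary=True)
    small = max_patch_size(r, 200.0).values
    big = max_patch_size(r, 500.0).values
    assert np.all(big >= small - 1e-12)


def test_focal_translation_invariance(rng):
    r = random_raster(rng, (10, 10), binary=True)
    shifted = Raster(r.values.copy(), r.cell_size, (5000.0, -3000.0),
                     r.nodata_mask.copy())
    np.testing.assert_array_equal(focal_statistic(r, 300.0, "percent_cover").values,
                                  focal_statistic(shifted, 300.0, "percent_cover").values)
    np.testing.assert_array_equal(edge_density(r, 300.0).values,
                                  edge_density(shifted, 300.0).values)


# ---------------------------------------------------------------------------
# stack assembly

def _base(rng, shape=(10, 10)):
    from maxscale.synthetic import LandscapeSpec, generate_landscape
    return generate_landscape(LandscapeSpec(shape=shape, seed=int(rng.integers(1e6))))


def test_stack_layer_counts(rng):
    base = _base(rng)
    full = build_variable_stack(base, ScaleSet((500.0, 1000.0, 1500.0, 2000.0,
                                                3000.0, 4000.0, 5000.0, 6000.0)))
    assert len(full.layers) == 13 * 8 + 2 == 106
    single = build_variable_stack(base, ScaleSet((500.0,)))
    assert len(single.layers) == 15
    assert "deciduous_cover@500" in single.layers and "dist_water" in single.layers


def test_stack_deterministic(rng):
    base = _base(rng)
    s1 = build_variable_stack(base, ScaleSet((500.0, 1000.0)))
    s2 = build_variable_stack(base, ScaleSet((500.0, 1000.0)))
    for name in s1.layers:
        np.testing.assert_array_equal(s1[name].values, s2[name].values)


def test_stack_missing_layer_errors(rng):
    base = _base(rng)
    del base["water"]
    with pytest.raises(KeyError):
        build_variable_stack(base, ScaleSet((500.0,)), variables=("water_cover",))
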