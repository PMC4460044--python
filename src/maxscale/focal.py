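"""Multi-scale raster variable construction.

Focal (moving-window) statistics, terrain slope/aspect, Euclidean
distance layers, woodland edge density and largest-patch metrics, and
the assembly of the full multi-scale variable stack.

Windows are circular by default: the window of cell *c* contains every
cell whose centre lies within ``radius_m`` of *c*'s centre.  Windows are
clipped at the raster border and around nodata cells — statistics are
taken over the valid in-window cells only.  Focal sums are computed with
exact row-run cumulative sums, so results agree with a brute-force
per-cell recomputation to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ASPECT_LEGEND, CategoricalRaster, Raster

__all__ = [
    "ScaleSet",
    "VariableStack",
    "window_offsets",
    "focal_statistic",
    "terrain_slope_aspect",
    "distance_to_feature",
    "edge_density",
    "max_patch_size",
    "build_variable_stack",
]

DEFAULT_SCALES_M = (500.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0)

#: the 13 scalar variables computed at every scale, plus how each is derived
SCALAR_VARIABLES = (
    "aspect_majority", "altitude_mean", "slope_mean",
    "water_cover", "deciduous_cover", "conifer_cover", "mixed_wood_cover",
    "building_cover", "manmade_cover", "ancient_wood_cover",
    "habitat_richness", "max_wood_patch", "wood_edge_density",
)
DISTANCE_VARIABLES = ("dist_water", "dist_wood_edge")


@dataclass(frozen=True)
class ScaleSet:
    """Ordered set of focal-window radii in metres."""

    radii_m: tuple[float, ...] = DEFAULT_SCALES_M

    def __post_init__(self) -> None:
        r = tuple(float(v) for v in self.radii_m)
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("scale radii must be strictly increasing")
        object.__setattr__(self, "radii_m", r)


@dataclass
class VariableStack:
    """Named set of candidate layers, all aligned to one grid.

    Keys are ``"variable@radius"`` for scalar variables (e.g.
    ``"deciduous_cover@1500"``) and the bare variable name for the
    scale-free distance layers.
    """

    layers: dict[str, Raster]
    categorical: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        for r in rasters[1:]:
            rasters[0].require_aligned(r)

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    def layer_name(self, variable: str, scale: float | None = None) -> str:
        if scale is None:
            return variable
        return f"{variable}@{int(scale)}"

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def variables(self) -> dict[str, list[float | None]]:
        """Map variable name -> sorted list of scales (None for distance layers)."""
        out: dict[str, list[float | None]] = {}
        for key in self.layers:
            if "@" in key:
                var, s = key.rsplit("@", 1)
                out.setdefault(var, []).append(float(s))
            else:
                out.setdefault(key, []).append(None)
        for v in out:
            if out[v] != [None]:
                out[v] = sorted(out[v])  # type: ignore[type-var]
        return out

    def valid_mask(self, names: list[str] | None = None) -> np.ndarray:
        names = list(self.layers) if names is None else names
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            mask &= self.layers[n].valid
        return mask

    def manifest(self) -> "list[dict]":
        rows = []
        for name in sorted(self.layers):
            rec = {"layer": name}
            rec.update(self.provenance.get(name, {}))
            rows.append(rec)
        return rows


# ---------------------------------------------------------------------------
# window geometry

def window_offsets(radius_m: float, cell_size: float, shape: str = "circle") -> np.ndarray:
    """(dy, dx) cell offsets whose centre lies within radius_m (or the square)."""
    if radius_m < cell_size:
        raise ValueError("window radius must be at least one cell")
    r = int(np.floor(radius_m / cell_size))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    if shape == "circle":
        keep = (dy ** 2 + dx ** 2) * cell_size ** 2 <= radius_m ** 2 + 1e-9
    elif shape == "square":
        keep = np.ones_like(dy, dtype=bool)
    else:
        raise ValueError(f"unknown window shape {shape!r}")
    return np.column_stack([dy[keep], dx[keep]])


def _row_runs(offsets: np.ndarray) -> list[tuple[int, int, int]]:
    """Decompose a window into horizontal runs (dy, dx_min, dx_max)."""
    runs = []
    for dy in np.unique(offsets[:, 0]):
        dxs = offsets[offsets[:, 0] == dy, 1]
        runs.append((int(dy), int(dxs.min()), int(dxs.max())))
    return runs


def focal_sum(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Exact windowed sum of ``values`` (zeros outside the grid)."""
    nr, nc = values.shape
    runs = _row_runs(offsets)
    ry = max(abs(r[0]) for r in runs)
    rx = max(max(abs(r[1]), abs(r[2])) for r in runs)
    pad = np.zeros((nr + 2 * ry, nc + 2 * rx + 1), dtype=float)
    pad[ry:ry + nr, rx + 1:rx + 1 + nc] = values
    csum = np.cumsum(pad, axis=1)
    out = np.zeros((nr, nc), dtype=float)
    for dy, lo, hi in runs:
        rows = slice(ry + dy, ry + dy + nr)
        out += csum[rows, rx + 1 + hi:rx + 1 + hi + nc]
        out -= csum[rows, rx + lo:rx + lo + nc]
    return out


# ---------------------------------------------------------------------------
# focal statistics

def focal_statistic(raster: Raster, radius_m: float, stat: str,
                    shape: str = "circle") -> Raster:
    """Per-cell window statistic.

    stat ``mean``            : mean of valid in-window values.
    stat ``percent_cover``   : 100 x fraction of valid in-window cells that
                               are 1 (input must be binary).
    stat ``majority``        : most frequent class code (categorical input);
                               ties broken by legend order.
    stat ``richness_proportion`` : 100 x (#distinct in-window codes) / (#legend classes).
    """
    offs = window_offsets(radius_m, raster.cell_size, shape)
    valid = raster.valid.astype(float)
    n_valid = focal_sum(valid, offs)
    empty = n_valid == 0

    if stat == "mean":
        s = focal_sum(np.where(raster.valid, raster.values, 0.0), offs)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s / n_valid
        out[empty] = 0.0
        return Raster(out, raster.cell_size, raster.origin, empty)

    if stat == "percent_cover":
        v = raster.values[raster.valid]
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("percent_cover requires a binary raster")
        s = focal_sum(np.where(raster.valid, raster.values, 0.0), offs)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * s / n_valid
        out[empty] = 0.0
        return Raster(out, raster.cell_size, raster.origin, empty)

    if stat in ("majority", "richness_proportion"):
        if not isinstance(raster, CategoricalRaster):
            raise ValueError(f"{stat} requires a categorical raster")
        codes = sorted(raster.legend)
        counts = np.stack([
            focal_sum(((raster.values == c) & raster.valid).astype(float), offs)
            for c in codes
        ])
        if stat == "majority":
            # argmax over the first axis; ties resolve to the earliest legend code
            win = np.argmax(counts, axis=0)
            out = np.asarray(codes, dtype=float)[win]
            out[empty] = 0.0
            return CategoricalRaster(out, raster.cell_size, raster.origin,
                                     empty, legend=dict(raster.legend))
        present = (counts > 0).sum(axis=0).astype(float)
        out = 100.0 * present / len(raster.legend)
        out[empty] = 0.0
        return Raster(out, raster.cell_size, raster.origin, empty)

    raise ValueError(f"unknown focal statistic {stat!r}")


# ---------------------------------------------------------------------------
# terrain

def _horn_gradient(z: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 weighted finite differences; borders fall back to one-sided
    differences via odd reflection (exact for planar surfaces)."""
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    # row 0 is north, so the northward derivative runs against the row index
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)
    return dzdx, dzdy


def terrain_slope_aspect(dem: Raster, flat_threshold_deg: float = 1.0
                         ) -> tuple[Raster, CategoricalRaster]:
    """Slope (degrees) and 8-class compass aspect from a DEM.

    Aspect is the downslope direction binned into 45-degree classes centred
    on N, NE, ... NW; cells flatter than ``flat_threshold_deg`` are "flat".
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = dem.values.copy()
    if dem.nodata_mask.any():
        # fill nodata from the nearest valid cell so gradients stay finite
        idx = ndimage.distance_transform_edt(dem.nodata_mask, return_distances=False,
                                             return_indices=True)
        z = z[tuple(idx)]
    dzdx, dzdy = _horn_gradient(z, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    east, north = -dzdx, -dzdy  # downslope vector components
    compass = (np.degrees(np.arctan2(east, north)) + 360.0) % 360.0
    classes = (np.round(compass / 45.0).astype(int) % 8) + 1
    classes[slope < flat_threshold_deg] = 0
    slope_r = Raster(slope, dem.cell_size, dem.origin, dem.nodata_mask.copy())
    aspect_r = CategoricalRaster(classes.astype(float), dem.cell_size, dem.origin,
                                 dem.nodata_mask.copy(), legend=dict(ASPECT_LEGEND))
    return slope_r, aspect_r


# ---------------------------------------------------------------------------
# distance, edges, patches

def distance_to_feature(feature: Raster) -> Raster:
    """Cell-centre Euclidean distance (metres) to the nearest feature cell."""
    feat = (feature.values != 0) & feature.valid
    if not feat.any():
        raise ValueError("no feature cells: distance undefined everywhere")
    dist = ndimage.distance_transform_edt(~feat, sampling=feature.cell_size)
    return Raster(dist, feature.cell_size, feature.origin, feature.nodata_mask.copy())


def _edge_length_per_cell(wood: Raster) -> np.ndarray:
    """Edge length attributed to each woodland cell: cell_size per shared
    boundary with a valid non-woodland rook neighbour."""
    w = (wood.values != 0) & wood.valid
    nonwood = (wood.values == 0) & wood.valid
    # rook-neighbour counts; grid borders contribute no edge
    nb_count = np.zeros(wood.shape, dtype=float)
    nb_count[1:, :] += nonwood[:-1, :]
    nb_count[:-1, :] += nonwood[1:, :]
    nb_count[:, 1:] += nonwood[:, :-1]
    nb_count[:, :-1] += nonwood[:, 1:]
    segs = np.where(w, nb_count, 0.0) * wood.cell_size
    return segs


def edge_density(wood: Raster, radius_m: float, shape: str = "circle") -> Raster:
    """Woodland edge length per unit area (km per km^2) in each window.

    An edge is the shared boundary segment between a woodland cell and a
    valid non-woodland cell; each segment is attributed to its woodland
    cell.  Window area is the valid in-window cell count times the cell
    area (clipped windows use their clipped area).
    """
    offs = window_offsets(radius_m, wood.cell_size, shape)
    segs_m = _edge_length_per_cell(wood)
    total_m = focal_sum(segs_m, offs)
    n_valid = focal_sum(wood.valid.astype(float), offs)
    empty = n_valid == 0
    area_km2 = n_valid * (wood.cell_size / 1000.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (total_m / 1000.0) / area_km2
    out[empty] = 0.0
    return Raster(out, wood.cell_size, wood.origin, empty)


def max_patch_size(wood: Raster, radius_m: float, shape: str = "circle",
                   connectivity: int = 8) -> Raster:
    """Area (km^2) of the largest woodland patch touching each window.

    Patches are connected components over the full raster (8-connectivity
    by default); a patch counts for a cell if at least one of its cells
    lies inside the cell's window.
    """
    offs = window_offsets(radius_m, wood.cell_size, shape)
    w = (wood.values != 0) & wood.valid
    structure = np.ones((3, 3), dtype=int) if connectivity == 8 else None
    labels, n = ndimage.label(w, structure=structure)
    area = np.zeros(wood.shape, dtype=float)
    if n:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        area = counts[labels] * (wood.cell_size / 1000.0) ** 2
    r = int(np.floor(radius_m / wood.cell_size))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    foot = np.zeros(dy.shape, dtype=bool)
    foot[tuple((offs + r).T)] = True
    out = ndimage.maximum_filter(area, footprint=foot, mode="constant", cval=0.0)
    return Raster(out, wood.cell_size, wood.origin, wood.nodata_mask.copy())


# ---------------------------------------------------------------------------
# stack assembly

def build_variable_stack(base: dict[str, Raster], scales: ScaleSet = ScaleSet(),
                         variables: tuple[str, ...] | None = None,
                         window_shape: str = "circle",
                         edge_distance_inside_zero: bool = True) -> VariableStack:
    """Assemble the multi-scale candidate-variable stack.

    ``base`` supplies the 100 m base rasters: ``dem``, a categorical
    ``habitat`` raster, and binary layers ``water``, ``deciduous``,
    ``conifer``, ``mixed_wood``, ``buildings``, ``manmade``,
    ``ancient_wood``.  Thirteen scalar variables are produced at every
    radius in ``scales`` plus the two scale-free distance layers; pass
    ``variables`` to restrict to a subset.
    """
    wanted = SCALAR_VARIABLES + DISTANCE_VARIABLES if variables is None else tuple(variables)
    unknown = set(wanted) - set(SCALAR_VARIABLES) - set(DISTANCE_VARIABLES)
    if unknown:
        raise KeyError(f"unknown variables requested: {sorted(unknown)}")

    rasters = list(base.values())
    for r in rasters[1:]:
        rasters[0].require_aligned(r)

    def need(name: str) -> Raster:
        if name not in base:
            raise KeyError(f"missing base layer {name!r}")
        return base[name]

    layers: dict[str, Raster] = {}
    cats: set[str] = set()
    prov: dict[str, dict] = {}

    def wood_mask() -> Raster:
        pieces = [need(n).values != 0 for n in ("deciduous", "conifer", "mixed_wood")
                  if n in base]
        if not pieces:
            raise KeyError("woodland variables need deciduous/conifer/mixed_wood layers")
        w = np.logical_or.reduce(pieces).astype(float)
        ref = need("deciduous") if "deciduous" in base else rasters[0]
        return Raster(w, ref.cell_size, ref.origin, ref.nodata_mask.copy())

    slope = aspect = None
    if "slope_mean" in wanted or "aspect_majority" in wanted:
        slope, aspect = terrain_slope_aspect(need("dem"))

    cover_sources = {
        "water_cover": "water", "deciduous_cover": "deciduous",
        "conifer_cover": "conifer", "mixed_wood_cover": "mixed_wood",
        "building_cover": "buildings", "manmade_cover": "manmade",
        "ancient_wood_cover": "ancient_wood",
    }

    for var in wanted:
        if var in DISTANCE_VARIABLES:
            if var == "dist_water":
                layer = distance_to_feature(need("water"))
                src = "water"
            else:
                wm = wood_mask()
                if edge_distance_inside_zero:
                    layer = distance_to_feature(wm)
                else:
                    edge_cells = _edge_length_per_cell(wm) > 0
                    layer = distance_to_feature(wm.copy_with(edge_cells.astype(float)))
                src = "woodland"
            layers[var] = layer
            prov[var] = {"variable": var, "scale": "", "statistic": "euclidean_distance",
                         "source": src}
            continue
        for radius in scales.radii_m:
            name = f"{var}@{int(radius)}"
            if var == "aspect_majority":
                layer = focal_statistic(aspect, radius, "majority", window_shape)
                cats.add(name)
                stat, src = "majority", "dem"
            elif var == "altitude_mean":
                layer = focal_statistic(need("dem"), radius, "mean", window_shape)
                stat, src = "mean", "dem"
            elif var == "slope_mean":
                layer = focal_statistic(slope, radius, "mean", window_shape)
                stat, src = "mean", "dem"
            elif var == "habitat_richness":
                layer = focal_statistic(need("habitat"), radius, "richness_proportion",
                                        window_shape)
                stat, src = "richness_proportion", "habitat"
            elif var == "max_wood_patch":
                layer = max_patch_size(wood_mask(), radius, window_shape)
                stat, src = "max_patch", "woodland"
            elif var == "wood_edge_density":
                layer = edge_density(wood_mask(), radius, window_shape)
                stat, src = "edge_density", "woodland"
            else:
                layer = focal_statistic(need(cover_sources[var]), radius,
                                        "percent_cover", window_shape)
                stat, src = "percent_cover", cover_sources[var]
            layers[name] = layer
            prov[name] = {"variable": var, "scale": int(radius), "statistic": stat,
                          "source": src}

    return VariableStack(layers, categorical=cats, provenance=prov)
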