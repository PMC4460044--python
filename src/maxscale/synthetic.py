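"""Synthetic landscapes and virtual species with known structure.

Generates a 100 m-resolution landscape mosaic (woodland classes, water,
buildings, manmade surfaces, a smooth DEM) as Gaussian-correlated random
fields thresholded to hit target cover fractions, plus virtual species
whose occurrence probability is a known function of chosen variables at
chosen scales, and a spatially biased observation process concentrated
around built areas.  Every pipeline stage can therefore be tested for
parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .focal import VariableStack, distance_to_feature
from .grid import CategoricalRaster, Raster, cell_centres, write_ascii_grid
from .occurrences import OccurrenceSet

__all__ = [
    "LandscapeSpec",
    "VirtualSpecies",
    "ObservationBias",
    "gaussian_field",
    "generate_landscape",
    "true_suitability",
    "sample_occurrences",
    "sample_weighted_cells",
    "building_access_bias",
    "uniform_bias",
    "make_fixture_study",
    "HABITAT_LEGEND",
]

#: 13-class habitat legend: 6 mapped landcover classes + 7 open classes
HABITAT_LEGEND = {
    1: "water", 2: "deciduous", 3: "conifer", 4: "mixed_wood",
    5: "buildings", 6: "manmade",
    7: "grassland", 8: "moorland", 9: "heath", 10: "bog",
    11: "scrub", 12: "arable", 13: "rock",
}

DEFAULT_COVER = {
    "water": 0.05, "deciduous": 0.12, "conifer": 0.08, "mixed_wood": 0.05,
    "buildings": 0.03, "manmade": 0.04,
}


@dataclass(frozen=True)
class LandscapeSpec:
    shape: tuple[int, int] = (150, 150)
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    correlation_length_m: float = 500.0
    target_cover: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVER))
    ancient_wood_fraction: float = 0.3   # of deciduous cells
    dem_relief_m: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.target_cover.values())
        if not 0 < total <= 1:
            raise ValueError("landcover fractions must be in (0, 1] in total")
        if any(not 0 < f < 1 for f in self.target_cover.values()):
            raise ValueError("each cover fraction must lie in (0, 1)")


def gaussian_field(shape: tuple[int, int], corr_len_cells: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian-correlated random field (mean 0, sd 1)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=max(corr_len_cells, 1e-6),
                                     mode="reflect")
    sd = smooth.std()
    return (smooth - smooth.mean()) / (sd if sd > 0 else 1.0)


def generate_landscape(spec: LandscapeSpec) -> dict[str, Raster]:
    """Base rasters for one synthetic study area.

    Landcover classes are assigned greedily from independent correlated
    fields: each class takes its top-scoring still-unassigned cells until
    its target cover is met (realised cover is exact to rounding, well
    within +-2% absolute).  Remaining cells become seven open-habitat
    classes split by elevation and a further field, giving the 13-class
    habitat raster.  The DEM is an independent smooth field scaled to
    ``dem_relief_m``.
    """
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.shape
    n = nr * nc
    sigma = spec.correlation_length_m / spec.cell_size

    dem = gaussian_field(spec.shape, sigma * 2, rng)
    dem = (dem - dem.min()) / (dem.max() - dem.min()) * spec.dem_relief_m

    codes = np.zeros(spec.shape, dtype=int)
    class_code = {name: code for code, name in HABITAT_LEGEND.items()}
    for name, frac in spec.target_cover.items():
        fld = gaussian_field(spec.shape, sigma, rng)
        want = int(round(frac * n))
        free = codes == 0
        scores = np.where(free, fld, -np.inf).ravel()
        take = np.argsort(scores)[::-1][:min(want, int(free.sum()))]
        codes.ravel()[take] = class_code[name]

    # open classes: split leftover cells by elevation terciles x field terciles
    open_codes = [7, 8, 9, 10, 11, 12, 13]
    leftover = np.flatnonzero(codes.ravel() == 0)
    mix = (0.6 * (dem.ravel()[leftover] / spec.dem_relief_m)
           + 0.4 * gaussian_field(spec.shape, sigma, rng).ravel()[leftover])
    order = np.argsort(mix, kind="stable")
    chunks = np.array_split(order, len(open_codes))
    for code, chunk in zip(open_codes, chunks):
        codes.ravel()[leftover[chunk]] = code

    base: dict[str, Raster] = {}
    mk = lambda v: Raster(v.astype(float), spec.cell_size, spec.origin)
    base["dem"] = mk(dem)
    base["habitat"] = CategoricalRaster(codes.astype(float), spec.cell_size,
                                        spec.origin, legend=dict(HABITAT_LEGEND))
    for name in DEFAULT_COVER:
        base[name] = mk(codes == class_code[name])

    # ancient woodland: a coherent subset of the deciduous cells
    anc_field = gaussian_field(spec.shape, sigma, rng)
    dec = codes == class_code["deciduous"]
    want = int(round(spec.ancient_wood_fraction * dec.sum()))
    scores = np.where(dec, anc_field, -np.inf).ravel()
    anc = np.zeros(n, dtype=bool)
    anc[np.argsort(scores)[::-1][:want]] = True
    base["ancient_wood"] = mk(anc.reshape(spec.shape))
    return base


@dataclass(frozen=True)
class ObservationBias:
    """Non-negative sampling-effort surface; ``mode`` is a label only."""

    surface: Raster
    mode: str = "biased"

    def __post_init__(self) -> None:
        v = self.surface.values[self.surface.valid]
        if not np.all(np.isfinite(v)) or not (v > 0).any():
            raise ValueError("bias surface must be finite and not all zero")


def building_access_bias(base: dict[str, Raster], decay_m: float = 1500.0,
                         floor: float = 0.02) -> ObservationBias:
    """Recorder-effort surface decaying with distance from buildings,
    emulating the access bias of volunteer-collected records."""
    dist = distance_to_feature(base["buildings"])
    surface = np.exp(-dist.values / decay_m) + floor
    return ObservationBias(dist.copy_with(surface), mode="biased")


def uniform_bias(grid: Raster) -> ObservationBias:
    return ObservationBias(grid.copy_with(np.ones(grid.shape)), mode="unbiased")


@dataclass(frozen=True)
class VirtualSpecies:
    """Known ground-truth response: product of per-layer response terms.

    Each term is (layer_name, shape, params); shapes are ``logistic_up``
    (params mid, rate), ``logistic_down`` and ``gaussian`` (params opt,
    sd).  The product is rescaled to [0, 1] over the valid cells.
    """

    name: str
    response_terms: tuple[tuple[str, str, tuple[float, ...]], ...]


def _term(values: np.ndarray, shape: str, params: tuple[float, ...]) -> np.ndarray:
    if shape == "logistic_up":
        mid, rate = params
        return 1.0 / (1.0 + np.exp(-(values - mid) / rate))
    if shape == "logistic_down":
        mid, rate = params
        return 1.0 / (1.0 + np.exp((values - mid) / rate))
    if shape == "gaussian":
        opt, sd = params
        return np.exp(-0.5 * ((values - opt) / sd) ** 2)
    raise ValueError(f"unknown response shape {shape!r}")


def true_suitability(species: VirtualSpecies, stack: VariableStack) -> Raster:
    """Ground-truth suitability in [0, 1] on the stack's grid."""
    grid = stack.grid
    out = np.ones(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    for layer, shape, params in species.response_terms:
        if layer not in stack.layers:
            raise KeyError(f"stack is missing layer {layer!r}")
        r = stack[layer]
        out = out * _term(r.values, shape, params)
        mask |= r.nodata_mask
    out[mask] = 0.0
    peak = out.max()
    if peak > 0:
        out = out / peak
    return Raster(out, grid.cell_size, grid.origin, mask)


def sample_weighted_cells(weights: Raster, n: int, seed: int,
                          jitter: bool = False) -> np.ndarray:
    """Draw n distinct cells with probability proportional to ``weights``
    and return their centre coordinates (Efraimidis-Spirakis keys, so the
    draw is without replacement and fully determined by the seed)."""
    w = np.where(weights.valid, weights.values, 0.0).ravel()
    w = np.clip(w, 0.0, None)
    positive = np.flatnonzero(w > 0)
    if len(positive) < n:
        raise ValueError(f"only {len(positive)} cells with positive weight, need {n}")
    rng = np.random.default_rng(seed)
    keys = np.full(w.shape, -np.inf)
    keys[positive] = np.log(rng.random(len(positive))) / w[positive]
    take = np.argsort(keys)[::-1][:n]
    rows, cols = np.unravel_index(take, weights.shape)
    xs, ys = cell_centres(weights)
    pts = np.column_stack([xs[rows, cols], ys[rows, cols]])
    if jitter:
        pts = pts + rng.uniform(-0.4, 0.4, pts.shape) * weights.cell_size
    return pts


def sample_occurrences(truth: Raster, bias: ObservationBias | None, n: int,
                       seed: int, species: str = "virtual") -> OccurrenceSet:
    """Presence records: cells drawn without replacement with probability
    proportional to (true suitability x observation effort); one record
    per cell by construction."""
    if n < 1:
        raise ValueError("n must be at least 1")
    w = truth.values.copy()
    if bias is not None:
        truth.require_aligned(bias.surface)
        w = w * bias.surface.values
    if not (w[truth.valid] > 0).any():
        raise ValueError("truth x bias has empty support")
    pts = sample_weighted_cells(truth.copy_with(w), n, seed)
    return OccurrenceSet(pts, species=species, role="presence")


def make_fixture_study(outdir: str | Path, spec: LandscapeSpec | None = None,
                       n_presence: int = 150, seed: int = 0) -> dict:
    """Write a small ready-to-run synthetic study (ASCII rasters + CSVs)."""
    from .focal import ScaleSet, build_variable_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or LandscapeSpec(seed=seed)
    base = generate_landscape(spec)
    for name, r in base.items():
        write_ascii_grid(r, outdir / f"{name}.asc")
    scales = ScaleSet((500.0, 1000.0, 1500.0, 2000.0))
    stack = build_variable_stack(base, scales,
                                 variables=("deciduous_cover", "water_cover",
                                            "altitude_mean", "dist_water"))
    species = VirtualSpecies("virtual", (("deciduous_cover@1500", "logistic_up",
                                          (12.0, 4.0)),))
    truth = true_suitability(species, stack)
    occ = sample_occurrences(truth, None, n_presence, seed=seed + 1)
    occ_df = pd.DataFrame({
        "species": species.name, "x": occ.points[:, 0], "y": occ.points[:, 1],
        "year": 2005, "month": 6, "activity": "day_roost", "id_method": "in_hand",
        "structure": "building", "precision_m": 100,
    })
    occ_df.to_csv(outdir / "occurrences.csv", index=False)
    write_ascii_grid(truth, outdir / "true_suitability.asc")
    return {"base": base, "stack": stack, "species": species, "truth": truth,
            "occurrences": occ}
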