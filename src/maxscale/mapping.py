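"""Projection of fitted models onto the raster stack and map comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .focal import VariableStack
from .grid import Raster, points_to_cells
from .maxent import MaxentModel, predict

__all__ = [
    "SuitabilityMap",
    "layer_table_at_points",
    "layer_table_all_cells",
    "predict_map",
    "niche_overlap_D",
]


def layer_table_at_points(stack: VariableStack, xy: np.ndarray,
                          layers: list[str] | None = None
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract layer values at points; returns (table, valid-row mask).

    Rows falling outside the grid or on any nodata cell are flagged
    invalid (and excluded from the table).
    """
    names = list(stack.layers) if layers is None else layers
    grid = stack.grid
    row, col = points_to_cells(xy, grid)
    ok = row >= 0
    data = {}
    for n in names:
        r = stack[n]
        vals = np.full(len(row), np.nan)
        vals[ok] = r.values[row[ok], col[ok]]
        invalid = np.zeros(len(row), dtype=bool)
        invalid[ok] = r.nodata_mask[row[ok], col[ok]]
        ok = ok & ~invalid
        data[n] = vals
    df = pd.DataFrame(data)
    return df.loc[ok].reset_index(drop=True), ok


def layer_table_all_cells(stack: VariableStack, layers: list[str] | None = None
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Table of layer values over every jointly valid cell, plus the 2-D
    boolean mask of those cells (row-major order matches the table)."""
    names = list(stack.layers) if layers is None else layers
    valid = stack.valid_mask(names)
    df = pd.DataFrame({n: stack[n].values[valid] for n in names})
    return df, valid


@dataclass
class SuitabilityMap:
    hsi: Raster
    species: str
    threshold: float

    @property
    def suitable_mask(self) -> Raster:
        vals = (self.hsi.values >= self.threshold).astype(float)
        vals[self.hsi.nodata_mask] = 0.0
        return self.hsi.copy_with(vals)

    @property
    def suitable_fraction(self) -> float:
        v = self.hsi.valid
        return float((self.hsi.values[v] >= self.threshold).mean())


def predict_map(model: MaxentModel, stack: VariableStack, species: str = "",
                threshold: float = 0.5) -> SuitabilityMap:
    """Per-cell logistic HSI over the stack; nodata wherever any input
    layer referenced by the model is nodata."""
    if model.builder is None:
        raise ValueError("model has no feature builder attached")
    names = model.builder.columns
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing layers: {missing}")
    table, valid = layer_table_all_cells(stack, names)
    hsi_vals = predict(model, model.builder.transform(table), "logistic")
    out = np.zeros(stack.grid.shape)
    out[valid] = hsi_vals
    hsi = Raster(out, stack.grid.cell_size, stack.grid.origin, ~valid)
    return SuitabilityMap(hsi, species, threshold)


def niche_overlap_D(map1: Raster | SuitabilityMap, map2: Raster | SuitabilityMap) -> float:
    """Schoener's D between two suitability surfaces.

    Each surface is normalised to sum 1 over the shared valid cells;
    D = 1 - 0.5 * sum |p_i - q_i|, so 1 means identical niches and 0
    disjoint ones.
    """
    r1 = map1.hsi if isinstance(map1, SuitabilityMap) else map1
    r2 = map2.hsi if isinstance(map2, SuitabilityMap) else map2
    r1.require_aligned(r2)
    shared = r1.valid & r2.valid
    p = r1.values[shared].astype(float)
    q = r2.values[shared].astype(float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("niche overlap undefined for an all-zero map")
    p = p / p.sum()
    q = q / q.sum()
    return float(1.0 - 0.5 * np.abs(p - q).sum())
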