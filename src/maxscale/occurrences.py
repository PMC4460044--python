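"""Occurrence-record filtering, thinning and pseudoabsence construction.

Raw record-centre exports are filtered down to species-specific summer
day-roost records (month window, per-species minimum year, identification
method, coordinate precision, study-region membership), thinned to one
record per grid cell, and contrasted against one of two pseudoabsence
schemes: a target group of similarly-surveyed records, or random
building centre-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Raster, points_to_cells

__all__ = [
    "FilterRules",
    "OccurrenceSet",
    "read_records_csv",
    "filter_records",
    "thin_one_per_cell",
    "target_group_pseudoabsences",
    "sample_building_pseudoabsences",
]

RECORD_COLUMNS = ["species", "x", "y", "year", "month", "activity",
                  "id_method", "structure", "precision_m"]


@dataclass
class FilterRules:
    """Record-retention predicates applied conjunctively.

    Defaults mirror a summer day-roost selection: April-September,
    in-hand or detector identification, 100 m coordinate precision.
    """

    months: tuple[int, int] = (4, 9)
    min_year: dict[str, int] = field(default_factory=dict)
    require_activity: set[str] | None = frozenset({"day_roost"})
    require_id_methods: set[str] | None = frozenset({"in_hand", "detector"})
    max_precision_m: float = 100.0
    structures: set[str] | None = None
    study_mask: Raster | None = None
    species_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.months
        if not (1 <= lo <= 12 and 1 <= hi <= 12):
            raise ValueError("months must lie in 1..12")
        if not self.max_precision_m > 0:
            raise ValueError("max_precision_m must be positive")


@dataclass
class OccurrenceSet:
    points: np.ndarray  # (n, 2) projected metres
    species: str
    role: str = "presence"  # or "pseudoabsence"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float)).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "x": self.points[:, 0],
                             "y": self.points[:, 1], "role": self.role})


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return df


def filter_records(records: pd.DataFrame, rules: FilterRules, species: str | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all retention predicates; return (retained, rejection log).

    The log is a two-column frame (predicate, count) giving how many
    records each predicate alone would reject, useful for auditing how a
    record set shrinks under the rules.
    """
    df = records.copy()
    if rules.species_aliases:
        df["species"] = df["species"].map(lambda s: rules.species_aliases.get(s, s))
    keep = np.ones(len(df), dtype=bool)
    log: list[tuple[str, int]] = []

    def apply(name: str, ok: np.ndarray) -> None:
        nonlocal keep
        log.append((name, int((~ok).sum())))
        keep &= ok

    if species is not None:
        target = rules.species_aliases.get(species, species)
        apply("species", (df["species"] == target).to_numpy())
    lo, hi = rules.months
    m = df["month"].to_numpy()
    apply("month_window", (m >= lo) & (m <= hi) if lo <= hi else (m >= lo) | (m <= hi))
    if rules.min_year:
        min_years = df["species"].map(lambda s: rules.min_year.get(s, -np.inf)).to_numpy()
        apply("min_year", df["year"].to_numpy() >= min_years)
    else:
        apply("min_year", np.ones(len(df), dtype=bool))
    if rules.require_activity is not None:
        apply("activity", df["activity"].isin(rules.require_activity).to_numpy())
    if rules.require_id_methods is not None:
        apply("id_method", df["id_method"].isin(rules.require_id_methods).to_numpy())
    apply("precision", (df["precision_m"].to_numpy() <= rules.max_precision_m))
    if rules.structures is not None:
        apply("structure", df["structure"].isin(rules.structures).to_numpy())
    if rules.study_mask is not None:
        pts = df[["x", "y"]].to_numpy()
        row, col = points_to_cells(pts, rules.study_mask)
        inside = row >= 0
        ok = inside.copy()
        ok[inside] = (rules.study_mask.values[row[inside], col[inside]] != 0) \
            & rules.study_mask.valid[row[inside], col[inside]]
        apply("study_region", ok)

    retained = df.loc[keep].reset_index(drop=True)
    return retained, pd.DataFrame(log, columns=["predicate", "count"])


def thin_one_per_cell(points: np.ndarray, cell_size: float,
                      origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Keep one point per occupied grid cell.

    Deterministic: points are sorted lexicographically by (x, y, input
    order) and the first point in each cell survives.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float)).reshape(-1, 2)
    if len(pts) == 0:
        return pts
    order = np.lexsort((np.arange(len(pts)), pts[:, 1], pts[:, 0]))
    pts = pts[order]
    cells = np.floor((pts - np.asarray(origin)) / cell_size).astype(np.int64)
    _, first = np.unique(cells, axis=0, return_index=True)
    return pts[np.sort(first)]


def target_group_pseudoabsences(records: pd.DataFrame, cell_size: float,
                                rules: FilterRules | None = None,
                                origin: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """Target-group scheme: all similarly-surveyed records (any species),
    filtered under relaxed rules and thinned to one per cell.  Because the
    target group shares the survey process, its spatial bias matches the
    presences' and cancels in the presence/background contrast."""
    if rules is None:
        rules = FilterRules(months=(1, 12), require_activity=None,
                            require_id_methods=None)
    kept, _ = filter_records(records, rules)
    pts = thin_one_per_cell(kept[["x", "y"]].to_numpy(), cell_size, origin)
    return OccurrenceSet(pts, species="target_group", role="pseudoabsence")


def sample_building_pseudoabsences(footprints: np.ndarray, n: int, seed: int,
                                   min_dims: tuple[float, float] = (10.0, 10.0),
                                   cell_size: float = 100.0,
                                   origin: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """Random building-centre pseudoabsences.

    ``footprints`` is an (n, 4) array of rectangles (xmin, ymin, xmax,
    ymax).  Buildings strictly larger than ``min_dims`` on both axes are
    reduced to centre-points, thinned to one per cell, and ``n`` are drawn
    uniformly without replacement under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    fp = np.atleast_2d(np.asarray(footprints, dtype=float)).reshape(-1, 4)
    w = fp[:, 2] - fp[:, 0]
    h = fp[:, 3] - fp[:, 1]
    qual = fp[(w > min_dims[0]) & (h > min_dims[1])]
    if len(qual) == 0:
        raise ValueError("no qualifying buildings")
    centres = np.column_stack([(qual[:, 0] + qual[:, 2]) / 2,
                               (qual[:, 1] + qual[:, 3]) / 2])
    centres = thin_one_per_cell(centres, cell_size, origin)
    rng = np.random.default_rng(seed)
    if len(centres) <= n:
        if len(centres) < n:
            import warnings
            warnings.warn(f"only {len(centres)} qualifying building cells for n={n}")
        chosen = centres
    else:
        idx = rng.choice(len(centres), size=n, replace=False)
        chosen = centres[np.sort(idx)]
    return OccurrenceSet(chosen, species="buildings", role="pseudoabsence")
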