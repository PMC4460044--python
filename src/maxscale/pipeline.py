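"""End-to-end study orchestration.

Runs the full modelling sequence in order — occurrence preparation,
pseudoabsence construction, multi-scale variable stack, univariate scale
scan, predictive-power screening, collinearity pruning, stepwise
backward selection, cross-validated evaluation with omission test and
residual correlogram, conditional spatially constrained re-validation,
and the final full-data model and suitability map — writing every
artefact (with the config and seeds embedded) into a run directory.

Inputs are either a synthetic study (landscape spec + virtual species,
all seeded) or files on disk (ASCII base rasters + an occurrence CSV).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .focal import ScaleSet, VariableStack, build_variable_stack
from .grid import Raster, read_ascii_grid, write_ascii_grid
from .mapping import layer_table_at_points, niche_overlap_D, predict_map
from .maxent import FeatureSpec, fit_sdm, permutation_importance
from .occurrences import (FilterRules, OccurrenceSet, filter_records,
                          read_records_csv, target_group_pseudoabsences,
                          thin_one_per_cell)
from .selection import (ModelLadder, prune_collinear, screen_variables,
                        stepwise_prune, univariate_scale_scan)
from .synthetic import (HABITAT_LEGEND, LandscapeSpec, VirtualSpecies,
                        building_access_bias, generate_landscape,
                        sample_occurrences, sample_weighted_cells,
                        true_suitability, uniform_bias)
from .validation import (SMALL_SAMPLE_CUTOFF, CVScheme, evaluate_model,
                         morans_correlogram)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (defaults follow the study design)."""

    # synthetic inputs (used when raster_dir is None)
    landscape: LandscapeSpec | None = None
    virtual_species: VirtualSpecies | None = None
    n_presence: int = 150
    observation: str = "unbiased"            # unbiased | biased
    # file inputs
    raster_dir: str | None = None
    records_csv: str | None = None
    species: str = "virtual"
    filter_rules: FilterRules | None = None
    # variables
    variables: tuple[str, ...] = ("deciduous_cover", "water_cover",
                                  "altitude_mean", "dist_water")
    scales: tuple[float, ...] = (500.0, 1000.0, 1500.0, 2000.0,
                                 3000.0, 4000.0, 5000.0, 6000.0)
    # pseudoabsences
    pseudoabsence_scheme: str = "target_group"   # target_group | random | buildings
    n_pseudoabsence: int = 2000
    # modelling
    beta_mult: float = 2.0
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    k_folds: int = 5
    small_sample_cutoff: int = SMALL_SAMPLE_CUTOFF
    auc_min: float = 0.5
    gain_min: float = 0.01
    r_max: float = 0.70
    n_perm: int = 9999
    correlogram_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d: dict = {}
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = list(v)
            d[k] = v
        if self.landscape is not None:
            d["landscape"] = asdict(self.landscape)
            d["landscape"]["shape"] = list(self.landscape.shape)
        if self.virtual_species is not None:
            d["virtual_species"] = {
                "name": self.virtual_species.name,
                "response_terms": [list(t) for t in self.virtual_species.response_terms],
            }
        return d


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def _load_base(config: PipelineConfig) -> dict[str, Raster]:
    if config.raster_dir is not None:
        base: dict[str, Raster] = {}
        for path in sorted(Path(config.raster_dir).glob("*.asc")):
            name = path.stem
            if name in ("true_suitability",):
                continue
            legend = HABITAT_LEGEND if name == "habitat" else None
            base[name] = read_ascii_grid(path, legend=legend)
        if not base:
            raise PipelineError("inputs", "no_rasters",
                                f"no .asc rasters in {config.raster_dir}")
        return base
    spec = config.landscape or LandscapeSpec(seed=config.seed)
    return generate_landscape(spec)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full study; returns the in-memory results and writes
    the run directory (reports, maps, model, log)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {"config": config}

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # ---- stage: inputs -------------------------------------------------
    base = _load_base(config)
    grid = next(iter(base.values()))
    _log(log, f"inputs: {len(base)} base rasters, grid {grid.shape[0]}x{grid.shape[1]} "
              f"at {grid.cell_size} m")

    # ---- stage: variable stack ----------------------------------------
    try:
        stack = build_variable_stack(base, ScaleSet(tuple(config.scales)),
                                     variables=config.variables)
    except KeyError as e:
        raise PipelineError("stack", "missing_layer", str(e)) from e
    pd.DataFrame(stack.manifest()).to_csv(out / "stack_manifest.csv", index=False)
    _log(log, f"stack: {len(stack.layers)} layers "
              f"({len(config.variables)} variables x {len(config.scales)} scales incl. "
              f"scale-free distance layers)")

    # ---- stage: occurrences -------------------------------------------
    bias = None
    truth = None
    if config.raster_dir is None or config.records_csv is None:
        if config.virtual_species is not None:
            vs = config.virtual_species
        else:
            # default truth: deciduous cover at 1500 m (or the nearest scale)
            s = min(config.scales, key=lambda v: abs(v - 1500.0))
            vs = VirtualSpecies(config.species,
                                ((f"deciduous_cover@{int(s)}", "logistic_up",
                                  (12.0, 4.0)),))
        truth = true_suitability(vs, stack)
        bias = (building_access_bias(base) if config.observation == "biased"
                else uniform_bias(grid))
        occ = sample_occurrences(truth, bias, config.n_presence,
                                 seed=config.seed + 11, species=vs.name)
        presences = occ.points
        _log(log, f"occurrences: sampled {len(presences)} virtual presences "
                  f"({config.observation} observation)")
        write_ascii_grid(truth, out / "true_suitability.asc")
    else:
        records = read_records_csv(config.records_csv)
        rules = config.filter_rules or FilterRules()
        kept, rejlog = filter_records(records, rules, species=config.species)
        rejlog.to_csv(out / "rejection_log.csv", index=False)
        presences = thin_one_per_cell(kept[["x", "y"]].to_numpy(), grid.cell_size,
                                      grid.origin)
        _log(log, f"occurrences: {len(records)} raw -> {len(kept)} filtered -> "
                  f"{len(presences)} thinned")
    presences = thin_one_per_cell(presences, grid.cell_size, grid.origin)
    if len(presences) < 2:
        raise PipelineError("occurrences", "too_few", f"{len(presences)} presences")

    # ---- stage: pseudoabsences ----------------------------------------
    scheme = config.pseudoabsence_scheme
    pa_seed = config.seed + 23
    if scheme == "target_group":
        if config.records_csv is not None and config.raster_dir is not None:
            records = read_records_csv(config.records_csv)
            pa = target_group_pseudoabsences(records, grid.cell_size,
                                             origin=grid.origin)
            pa_points = pa.points
        else:
            eff = bias if bias is not None else uniform_bias(grid)
            pa_points = sample_weighted_cells(eff.surface, config.n_pseudoabsence,
                                              seed=pa_seed)
    elif scheme == "random":
        flat = uniform_bias(grid)
        pa_points = sample_weighted_cells(flat.surface, config.n_pseudoabsence,
                                          seed=pa_seed)
    elif scheme == "buildings":
        if "buildings" not in base:
            raise PipelineError("pseudoabsences", "missing_layer",
                                "buildings raster required for building scheme")
        pa_points = sample_weighted_cells(base["buildings"], config.n_pseudoabsence,
                                          seed=pa_seed)
    else:
        raise PipelineError("pseudoabsences", "unknown_scheme", scheme)
    pa_points = thin_one_per_cell(pa_points, grid.cell_size, grid.origin)
    _log(log, f"pseudoabsences: {scheme}, {len(pa_points)} points")

    OccurrenceSet(presences, config.species).to_frame().to_csv(
        out / "presences.csv", index=False)
    OccurrenceSet(pa_points, scheme, "pseudoabsence").to_frame().to_csv(
        out / "pseudoabsences.csv", index=False)

    # ---- stage: layer tables ------------------------------------------
    pres_tbl, pres_ok = layer_table_at_points(stack, presences)
    pa_tbl, _ = layer_table_at_points(stack, pa_points)
    presence_xy = presences[pres_ok]
    n = len(pres_tbl)
    if n < 2:
        raise PipelineError("occurrences", "all_nodata",
                            "presences have no valid layer overlap")

    small = n < config.small_sample_cutoff
    cv = CVScheme.for_sample_size(n, k=config.k_folds, seed=config.seed + 31)
    _log(log, f"validation scheme: {cv.mode} (n={n})")

    # ---- stage: univariate scale scan ---------------------------------
    scan = univariate_scale_scan(pres_tbl, pa_tbl, stack.variables(), presence_xy,
                                 cv, categorical=stack.categorical,
                                 spec=config.feature_spec, beta_mult=config.beta_mult)
    pd.DataFrame([row for r in scan for row in r.to_rows()]).to_csv(
        out / "scan.csv", index=False)
    _log(log, "scale scan: best scales "
              + ", ".join(f"{r.variable}@{r.best_scale}" for r in scan))

    # ---- stage: screening + collinearity ------------------------------
    try:
        screened = screen_variables(scan, config.auc_min, config.gain_min)
    except ValueError as e:
        raise PipelineError("screening", "empty_ladder", str(e)) from e
    decorrelated = prune_collinear(screened, stack, config.r_max)
    _log(log, f"screening: {len(scan)} -> {len(screened)} variables; "
              f"collinearity: -> {len(decorrelated)}")

    # ---- stage: stepwise pruning --------------------------------------
    layers = [r.best_layer for r in decorrelated]
    step = stepwise_prune(layers, pres_tbl, pa_tbl, presence_xy, cv,
                          categorical=stack.categorical, spec=config.feature_spec,
                          beta_mult=config.beta_mult, small_sample=small)
    step.steps.to_csv(out / "ladder.csv", index=False)
    ladder = ModelLadder(
        full_set=[r.best_layer for r in scan],
        screened_set=[r.best_layer for r in screened],
        decorrelated_set=layers,
        pruned_set=step.best_layers,
        scan=scan, stepwise=step)
    _log(log, f"stepwise: pruned set = {'+'.join(step.best_layers)}")

    # ---- stage: evaluation --------------------------------------------
    report = step.best_report
    pd.DataFrame([report.summary()]).to_csv(out / "evaluation.csv", index=False)
    report.folds.to_csv(out / "evaluation_folds.csv", index=False)

    # residual correlogram on the full-data model
    final = fit_sdm(pres_tbl[step.best_layers],
                    pd.concat([pa_tbl[step.best_layers],
                               pres_tbl[step.best_layers]], ignore_index=True),
                    categorical=stack.categorical & set(step.best_layers),
                    spec=config.feature_spec, beta_mult=config.beta_mult)
    from .maxent import predict as _predict
    hsi_at_pres = _predict(final, final.builder.transform(pres_tbl[step.best_layers]),
                           "logistic")
    residuals = 1.0 - hsi_at_pres
    correlogram = None
    if len(presence_xy) >= 4 and residuals.std() > 0:
        correlogram = morans_correlogram(residuals, presence_xy,
                                         n_perm=config.n_perm,
                                         seed=config.seed + 47,
                                         alpha=config.correlogram_alpha)
        correlogram.to_frame().to_csv(out / "correlogram.csv", index=False)
        report.correlogram = correlogram
        _log(log, f"correlogram: rSAC lag = {correlogram.rsac_lag_km} km")
    else:
        _log(log, "correlogram: skipped (degenerate residuals or too few points)")

    # ---- stage: conditional spatial re-validation ---------------------
    spatial_report = None
    rsac = correlogram is not None and correlogram.rsac_lag_km is not None
    if rsac and n >= config.small_sample_cutoff:
        cv_sp = CVScheme("kfold_spatial", k=config.k_folds, seed=config.seed + 53)
        spatial_report = evaluate_model(pres_tbl[step.best_layers],
                                        pa_tbl[step.best_layers], presence_xy,
                                        cv_sp,
                                        categorical=stack.categorical & set(step.best_layers),
                                        spec=config.feature_spec,
                                        beta_mult=config.beta_mult)
        pd.DataFrame([spatial_report.summary()]).to_csv(
            out / "evaluation_spatial.csv", index=False)
        _log(log, "spatial re-validation: run (rSAC detected)")
    else:
        _log(log, "spatial re-validation: skipped "
                  + ("(no rSAC)" if not rsac else "(small sample)"))

    # ---- stage: final model + map -------------------------------------
    smap = predict_map(final, stack, species=config.species,
                       threshold=report.threshold)
    write_ascii_grid(smap.hsi, out / "hsi.asc")
    write_ascii_grid(smap.suitable_mask, out / "suitable.asc")
    with open(out / "model.json", "w") as fh:
        json.dump(final.to_dict(), fh, sort_keys=True, indent=1)
    imp = permutation_importance(final, pres_tbl[step.best_layers],
                                 pa_tbl[step.best_layers], seed=config.seed + 61)
    pd.DataFrame(sorted(imp.items()), columns=["variable", "percent"]).to_csv(
        out / "importance.csv", index=False)
    _log(log, f"map: suitable fraction {smap.suitable_fraction:.4f} at "
              f"threshold {report.threshold:.4f}")

    if truth is not None:
        from scipy.stats import spearmanr
        shared = smap.hsi.valid & truth.valid
        rho = float(spearmanr(smap.hsi.values[shared], truth.values[shared]).statistic)
        _log(log, f"truth check: Spearman rho(HSI, true suitability) = {rho:.4f}")
        results["truth_rank_corr"] = rho
        results["truth"] = truth

    (out / "log.txt").write_text("\n".join(log) + "\n")
    results.update({
        "base": base, "stack": stack, "presences": presence_xy,
        "pseudoabsences": pa_points, "scan": scan, "ladder": ladder,
        "report": report, "spatial_report": spatial_report,
        "correlogram": correlogram, "model": final, "map": smap,
        "log": log,
    })
    return results
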