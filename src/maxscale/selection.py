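"""The univariate-to-multivariate model-selection ladder.

Every candidate variable is first fitted alone at each spatial scale and
its best scale kept (highest cross-validated test AUC, ties to the
smallest scale).  Variables failing the predictive-power screen (test
AUC <= 0.5 or test gain <= 0.01) are removed; survivors are checked for
collinearity over the study-area cells (|r| >= 0.70 drops the
lower-AUC member of each pair, strongest pairs first); the remainder is
reduced by a jackknife leave-one-out stepwise backward search, keeping
the candidate set with the best cross-validated performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .focal import VariableStack
from .maxent import FeatureSpec
from .validation import CVScheme, EvaluationReport, evaluate_model

__all__ = [
    "ScaleScanResult",
    "ModelLadder",
    "StepwiseResult",
    "univariate_scale_scan",
    "screen_variables",
    "prune_collinear",
    "stepwise_prune",
]


@dataclass
class ScaleScanResult:
    variable: str
    per_scale: dict[float | None, tuple[float, float]]  # scale -> (test AUC, test gain)
    best_scale: float | None

    @property
    def best_auc(self) -> float:
        return self.per_scale[self.best_scale][0]

    @property
    def best_gain(self) -> float:
        return self.per_scale[self.best_scale][1]

    @property
    def best_layer(self) -> str:
        if self.best_scale is None:
            return self.variable
        return f"{self.variable}@{int(self.best_scale)}"

    def to_rows(self) -> list[dict]:
        return [{"variable": self.variable,
                 "scale": "" if s is None else int(s),
                 "test_auc": a, "test_gain": g,
                 "best": s == self.best_scale}
                for s, (a, g) in self.per_scale.items()]


def univariate_scale_scan(pres_layers: pd.DataFrame, pa_layers: pd.DataFrame,
                          variables: dict[str, list[float | None]],
                          presence_xy: np.ndarray, scheme: CVScheme,
                          categorical: set[str] = frozenset(),
                          spec: FeatureSpec = FeatureSpec(),
                          beta_mult: float = 2.0) -> list[ScaleScanResult]:
    """Cross-validated univariate fit of every variable at every scale.

    ``variables`` maps variable name to its list of scales (``[None]``
    for the scale-free distance layers); layer tables must hold one
    column per (variable, scale) layer.  The best scale maximises mean
    test AUC; ties break to the smallest scale.
    """
    results = []
    for var, scales in variables.items():
        per_scale: dict[float | None, tuple[float, float]] = {}
        best, best_auc = None, -np.inf
        for s in scales:
            col = var if s is None else f"{var}@{int(s)}"
            rep = evaluate_model(pres_layers[[col]], pa_layers[[col]], presence_xy,
                                 scheme, categorical=categorical & {col},
                                 spec=spec, beta_mult=beta_mult)
            per_scale[s] = (rep.test_auc, rep.test_gain)
            if rep.test_auc > best_auc + 1e-12:  # strict: ties keep the smaller scale
                best, best_auc = s, rep.test_auc
        results.append(ScaleScanResult(var, per_scale, best))
    return results


def screen_variables(results: list[ScaleScanResult], auc_min: float = 0.5,
                     gain_min: float = 0.01) -> list[ScaleScanResult]:
    """Drop variables whose best-scale univariate test AUC <= auc_min or
    test gain <= gain_min (both gates are strict retain-if-greater)."""
    kept = [r for r in results if r.best_auc > auc_min and r.best_gain > gain_min]
    if not kept:
        raise ValueError("screening removed every variable: empty model ladder")
    return kept


def prune_collinear(candidates: list[ScaleScanResult], stack: VariableStack,
                    r_max: float = 0.70) -> list[ScaleScanResult]:
    """Greedy collinearity pruning over the study-area cells.

    Pearson r between each pair of best-scale layers is computed over all
    jointly valid cells; while any pair has |r| >= r_max, the strongest
    such pair is resolved by dropping its lower-AUC member.
    """
    if not candidates:
        raise ValueError("no candidate variables")
    layers = [c.best_layer for c in candidates]
    table, _ = _layer_matrix(stack, layers)
    r = np.corrcoef(table.T) if len(layers) > 1 else np.ones((1, 1))
    r = np.atleast_2d(r)
    alive = list(range(len(candidates)))
    while True:
        worst, w_abs = None, -1.0
        for ii, i in enumerate(alive):
            for j in alive[ii + 1:]:
                if abs(r[i, j]) >= r_max - 1e-12 and abs(r[i, j]) > w_abs:
                    worst, w_abs = (i, j), abs(r[i, j])
        if worst is None:
            break
        i, j = worst
        drop = j if candidates[i].best_auc >= candidates[j].best_auc else i
        alive.remove(drop)
    return [candidates[i] for i in alive]


def _layer_matrix(stack: VariableStack, layers: list[str]) -> tuple[np.ndarray, np.ndarray]:
    valid = stack.valid_mask(layers)
    return np.column_stack([stack[n].values[valid] for n in layers]), valid


@dataclass
class StepwiseResult:
    steps: pd.DataFrame                       # one row per evaluated candidate set
    best_layers: list[str]
    best_report: EvaluationReport
    n_refits: int


@dataclass
class ModelLadder:
    full_set: list[str]
    screened_set: list[str]
    decorrelated_set: list[str]
    pruned_set: list[str]
    scan: list[ScaleScanResult] = field(default_factory=list)
    stepwise: StepwiseResult | None = None

    def check_monotone(self) -> bool:
        return (set(self.screened_set) <= set(self.full_set)
                and set(self.decorrelated_set) <= set(self.screened_set)
                and set(self.pruned_set) <= set(self.decorrelated_set)
                and len(self.pruned_set) >= 1)


def stepwise_prune(layers: list[str], pres_layers: pd.DataFrame,
                   pa_layers: pd.DataFrame, presence_xy: np.ndarray,
                   scheme: CVScheme, categorical: set[str] = frozenset(),
                   spec: FeatureSpec = FeatureSpec(), beta_mult: float = 2.0,
                   small_sample: bool | None = None,
                   full_report: EvaluationReport | None = None) -> StepwiseResult:
    """Jackknife leave-one-out backward pruning.

    At each step the variable whose removal least harms (or most helps)
    mean test AUC is dropped, down to a single variable; every candidate
    set along the way is recorded.  The final choice maximises mean test
    AUC, or — for small samples (n < 25) — minimises omission rate, then
    its p-value, with test AUC as the tie-break.
    """
    if not layers:
        raise ValueError("no variables to prune")
    if small_sample is None:
        small_sample = len(pres_layers) < 25

    def ev(subset: list[str]) -> EvaluationReport:
        return evaluate_model(pres_layers[subset], pa_layers[subset], presence_xy,
                              scheme, categorical=set(categorical) & set(subset),
                              spec=spec, beta_mult=beta_mult)

    n_refits = 0
    if full_report is None:
        full_report = ev(list(layers))
        n_refits += 1
    candidates: list[tuple[list[str], EvaluationReport]] = [(list(layers), full_report)]
    current = list(layers)
    current_rep = full_report
    while len(current) > 1:
        best_v, best_rep = None, None
        for v in current:
            subset = [w for w in current if w != v]
            rep = ev(subset)
            n_refits += 1
            if best_rep is None or rep.test_auc > best_rep.test_auc + 1e-12:
                best_v, best_rep = v, rep
        current = [w for w in current if w != best_v]
        current_rep = best_rep
        candidates.append((current, current_rep))

    def key(item: tuple[list[str], EvaluationReport]):
        rep = item[1]
        if small_sample:
            return (round(rep.omission_rate, 12), round(rep.p_omission, 12),
                    -rep.test_auc)
        return (-rep.test_auc,)

    best_layers, best_report = min(candidates, key=key)
    steps = pd.DataFrame([{
        "step": i, "n_vars": len(ls), "variables": "+".join(ls),
        "train_auc": rep.train_auc, "test_auc": rep.test_auc,
        "test_gain": rep.test_gain, "omission_rate": rep.omission_rate,
        "p_omission": rep.p_omission,
        "selected": ls == best_layers,
    } for i, (ls, rep) in enumerate(candidates)])
    return StepwiseResult(steps, list(best_layers), best_report, n_refits)
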