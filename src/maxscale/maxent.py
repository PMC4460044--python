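"""Presence-background maximum-entropy (Gibbs) estimator.

The model places a probability mass ``raw(x) = exp(lambda . f(x)) / Z``
on every background cell, where ``f`` is a vector of features built from
the environmental variables and ``Z`` normalises over the background.
Weights maximise the L1-penalised log-likelihood of the presence cells

    L(lambda) = mean_presence[lambda . f(x)] - log Z(lambda)
                - sum_j beta_j |lambda_j|

which is concave; the fit is a deterministic box-constrained
quasi-Newton optimisation of the equivalent smooth split-weight problem.
The habitat suitability index (HSI) is the logistic transform
``e^H raw / (1 + e^H raw)`` with ``H`` the entropy of the fitted
distribution over the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

__all__ = [
    "FeatureSpec",
    "FeatureDef",
    "FeatureBuilder",
    "MaxentModel",
    "auto_feature_classes",
    "fit_maxent",
    "fit_sdm",
    "predict",
    "gain",
    "auc",
    "permutation_importance",
]

#: default class-level regularisation constants, interpolated against the
#: presence sample size m (reference-implementation defaults; config-exposed)
REG_TABLES: dict[str, tuple[list[float], list[float]]] = {
    "linear": ([10, 30, 100], [1.0, 1.0, 1.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
}

#: floor on the presence standard deviation entering the penalty, so that
#: features constant across presences keep a non-zero penalty
S_FLOOR = 1e-3


def auto_feature_classes(n_presence: int) -> set[str]:
    """Sample-size-dependent default feature classes."""
    if n_presence < 10:
        classes = {"linear"}
    elif n_presence < 15:
        classes = {"linear", "quadratic"}
    elif n_presence < 80:
        classes = {"linear", "quadratic", "hinge"}
    else:
        classes = {"linear", "quadratic", "hinge", "product", "threshold"}
    classes.add("categorical")
    return classes


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand variables into.

    ``classes=None`` (with ``auto_by_n``) selects classes from the
    presence sample size.  ``knots`` interior knots are used for hinge
    and threshold features, evenly spaced on the scaled [0, 1] range.
    """

    classes: frozenset[str] | None = None
    knots: int = 5
    auto_by_n: bool = True

    def resolve(self, n_presence: int) -> set[str]:
        if self.classes is not None:
            if not self.classes:
                raise ValueError("at least one feature class required")
            return set(self.classes)
        if not self.auto_by_n:
            raise ValueError("classes=None requires auto_by_n")
        return auto_feature_classes(n_presence)


class FeatureDef(NamedTuple):
    kind: str            # linear/quadratic/product/hinge/threshold/categorical
    var: str
    var2: str | None = None   # second variable for products
    knot: float | None = None  # hinge/threshold knot or categorical code


class FeatureBuilder:
    """Expands a variable table into the model's feature matrix.

    Continuous variables are min-max scaled to [0, 1] using background
    extremes recorded at construction; categorical variables become one
    indicator per code observed in the background.
    """

    def __init__(self, background: pd.DataFrame, categorical: set[str] = frozenset(),
                 spec: FeatureSpec = FeatureSpec(), n_presence: int = 100):
        self.columns = list(background.columns)
        self.categorical = set(categorical) & set(background.columns)
        self.continuous = [c for c in background.columns if c not in self.categorical]
        self.classes = spec.resolve(n_presence)
        self.spec = spec
        self.ranges = {c: (float(background[c].min()), float(background[c].max()))
                       for c in self.continuous}
        self.cat_codes = {c: sorted(int(v) for v in background[c].unique())
                          for c in sorted(self.categorical)}
        self.defs = self._make_defs()

    def _make_defs(self) -> list[FeatureDef]:
        defs: list[FeatureDef] = []
        knots = [(j + 1) / (self.spec.knots + 1) for j in range(self.spec.knots)]
        cont = [c for c in self.continuous if self.ranges[c][1] > self.ranges[c][0]]
        if "linear" in self.classes:
            defs += [FeatureDef("linear", c) for c in cont]
        if "quadratic" in self.classes:
            defs += [FeatureDef("quadratic", c) for c in cont]
        if "product" in self.classes:
            for i, a in enumerate(cont):
                for b in cont[i + 1:]:
                    defs.append(FeatureDef("product", a, var2=b))
        if "hinge" in self.classes:
            defs += [FeatureDef("hinge", c, knot=k) for c in cont for k in knots]
        if "threshold" in self.classes:
            defs += [FeatureDef("threshold", c, knot=k) for c in cont for k in knots]
        if "categorical" in self.classes:
            for c, codes in self.cat_codes.items():
                defs += [FeatureDef("categorical", c, knot=float(code)) for code in codes]
        return defs

    def scale(self, df: pd.DataFrame) -> dict[str, np.ndarray]:
        out = {}
        for c in self.continuous:
            lo, hi = self.ranges[c]
            v = df[c].to_numpy(dtype=float)
            out[c] = np.zeros_like(v) if hi <= lo else np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        return out

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        scaled = self.scale(df)
        cols = []
        for d in self.defs:
            if d.kind == "linear":
                cols.append(scaled[d.var])
            elif d.kind == "quadratic":
                cols.append(scaled[d.var] ** 2)
            elif d.kind == "product":
                cols.append(scaled[d.var] * scaled[d.var2])
            elif d.kind == "hinge":
                cols.append(np.maximum(0.0, (scaled[d.var] - d.knot) / (1.0 - d.knot)))
            elif d.kind == "threshold":
                cols.append((scaled[d.var] > d.knot).astype(float))
            elif d.kind == "categorical":
                cols.append((df[d.var].to_numpy(dtype=float) == d.knot).astype(float))
            else:  # pragma: no cover
                raise ValueError(d.kind)
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)


@dataclass
class MaxentModel:
    feature_defs: list[FeatureDef]
    weights: np.ndarray
    logZ: float
    entropy: float
    beta: np.ndarray
    n_background: int
    beta_mult: float = 2.0
    converged: bool = True
    builder: FeatureBuilder | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "feature_defs": [list(fd) for fd in self.feature_defs],
            "weights": self.weights.tolist(),
            "logZ": self.logZ, "entropy": self.entropy,
            "beta": self.beta.tolist(), "n_background": self.n_background,
            "beta_mult": self.beta_mult,
        }
        if self.builder is not None:
            d["scaling"] = self.builder.ranges
        return d


def default_beta(defs: list[FeatureDef], presence_F: np.ndarray,
                 beta_mult: float = 2.0) -> np.ndarray:
    """Per-feature L1 penalty: beta_mult x class constant x s_j / sqrt(m)."""
    m = len(presence_F)
    s = presence_F.std(axis=0) if m > 1 else np.zeros(len(defs))
    s = np.maximum(s, S_FLOOR)
    out = np.empty(len(defs))
    for j, d in enumerate(defs):
        xs, ys = REG_TABLES[d.kind]
        out[j] = beta_mult * np.interp(m, xs, ys) * s[j] / np.sqrt(max(m, 1))
    return out


def fit_maxent(presence_F: np.ndarray, background_F: np.ndarray,
               defs: list[FeatureDef] | None = None,
               beta: np.ndarray | float | None = None, beta_mult: float = 2.0,
               tol: float = 1e-10, max_iter: int = 1000) -> MaxentModel:
    """Fit the penalised Gibbs model over the background cells.

    ``beta`` overrides the default per-feature penalties (scalar or
    per-feature array); the default follows the class-level constants in
    ``REG_TABLES`` scaled by ``beta_mult``.
    """
    P = np.atleast_2d(np.asarray(presence_F, dtype=float))
    B = np.atleast_2d(np.asarray(background_F, dtype=float))
    if len(P) < 1 or len(B) < 2:
        raise ValueError("need >=1 presence and >=2 background rows")
    k = P.shape[1]
    if defs is None:
        defs = [FeatureDef("linear", f"f{j}") for j in range(k)]
    if beta is None:
        beta_vec = default_beta(defs, P, beta_mult)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (k,)).copy()

    if k == 0:
        logZ = float(np.log(len(B)))
        return MaxentModel(defs, np.empty(0), logZ, logZ, beta_vec, len(B), beta_mult)

    pmean = P.mean(axis=0)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        lam = x[:k] - x[k:]
        u = B @ lam
        logZ = logsumexp(u)
        p = np.exp(u - logZ)
        grad_lam = B.T @ p - pmean
        val = logZ - pmean @ lam + beta_vec @ (x[:k] + x[k:])
        grad = np.concatenate([grad_lam + beta_vec, -grad_lam + beta_vec])
        return float(val), grad

    res = minimize(objective, np.zeros(2 * k), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * k),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    lam = res.x[:k] - res.x[k:]
    u = B @ lam
    logZ = float(logsumexp(u))
    p = np.exp(u - logZ)
    entropy = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    return MaxentModel(defs, lam, logZ, entropy, beta_vec, len(B), beta_mult,
                       converged=bool(res.success))


def fit_sdm(presences: pd.DataFrame, background: pd.DataFrame,
            categorical: set[str] = frozenset(), spec: FeatureSpec = FeatureSpec(),
            beta_mult: float = 2.0, **fit_kw) -> MaxentModel:
    """Fit from variable tables: builds features (scaled on the background,
    which should include the presence cells) and fits the Gibbs model."""
    builder = FeatureBuilder(background, categorical, spec, n_presence=len(presences))
    model = fit_maxent(builder.transform(presences), builder.transform(background),
                       defs=builder.defs, beta_mult=beta_mult, **fit_kw)
    model.builder = builder
    return model


def _linear_predictor(model: MaxentModel, F: np.ndarray) -> np.ndarray:
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if len(model.weights) == 0:
        return np.zeros(len(F))
    return F @ model.weights


def predict(model: MaxentModel, F: np.ndarray, output: str = "logistic") -> np.ndarray:
    """Raw probability mass or logistic HSI for feature rows ``F``."""
    if F.ndim == 2 and F.shape[1] != len(model.weights):
        raise ValueError("feature dimensionality mismatch")
    raw = np.exp(_linear_predictor(model, F) - model.logZ)
    if output == "raw":
        return raw
    if output == "logistic":
        eH = np.exp(model.entropy)
        return eH * raw / (1.0 + eH * raw)
    raise ValueError(f"unknown output {output!r}")


def predict_vars(model: MaxentModel, df: pd.DataFrame, output: str = "logistic") -> np.ndarray:
    if model.builder is None:
        raise ValueError("model has no feature builder attached")
    return predict(model, model.builder.transform(df), output)


def gain(model: MaxentModel, presence_F: np.ndarray, penalised: bool = False) -> float:
    """Mean log improvement over the uniform background distribution at the
    given presence rows; optionally minus the L1 penalty (training gain)."""
    P = np.atleast_2d(np.asarray(presence_F, dtype=float))
    if len(P) < 1:
        raise ValueError("need at least one presence row")
    raw = np.exp(_linear_predictor(model, P) - model.logZ)
    if np.any(raw <= 0):
        raise FloatingPointError("zero raw probability at a presence")
    g = float(np.mean(np.log(raw * model.n_background)))
    if penalised:
        g -= float(model.beta @ np.abs(model.weights))
    return g


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: P(presence score > background score), ties 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("empty score list")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


def permutation_importance(model: MaxentModel, presences: pd.DataFrame,
                           background: pd.DataFrame, seed: int = 0) -> dict[str, float]:
    """Percent contribution of each variable: normalised drop in training
    AUC after permuting that variable across presence + background rows."""
    if model.builder is None:
        raise ValueError("model has no feature builder attached")
    rng = np.random.default_rng(seed)
    both = pd.concat([presences, background], ignore_index=True)
    n_p = len(presences)
    base_scores = predict_vars(model, both, output="raw")
    base = auc(base_scores[:n_p], base_scores[n_p:])
    drops = {}
    for var in both.columns:
        shuffled = both.copy()
        shuffled[var] = rng.permutation(shuffled[var].to_numpy())
        s = predict_vars(model, shuffled, output="raw")
        drops[var] = max(0.0, base - auc(s[:n_p], s[n_p:]))
    total = sum(drops.values())
    if total == 0:
        return {v: 100.0 / len(drops) for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}
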