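"""Model validation: cross-validation folds, thresholding, omission tests
and Moran's I correlograms on model residuals.

Fold schemes follow the sample-size rule of the study design: random
5-fold cross-validation for 25 or more presence records, leave-one-out
jackknife below 25.  When residual spatial autocorrelation is detected,
folds can instead be spatially aggregated (seeded k-means on the point
coordinates) so that train and test subsets are pushed apart in space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.cluster import KMeans

from .maxent import FeatureSpec, MaxentModel, auc, fit_sdm, gain, predict

__all__ = [
    "CVScheme",
    "EvaluationReport",
    "CorrelogramResult",
    "make_folds",
    "inter_fold_distances",
    "threshold_max_sens_spec",
    "omission_test",
    "morans_correlogram",
    "evaluate_model",
    "SMALL_SAMPLE_CUTOFF",
]

#: below this many presence records, jackknife validation replaces 5-fold CV
SMALL_SAMPLE_CUTOFF = 25


@dataclass(frozen=True)
class CVScheme:
    mode: str = "kfold_random"  # kfold_random | jackknife | kfold_spatial
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"kfold_random", "jackknife", "kfold_spatial"}:
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.mode != "jackknife" and self.k < 2:
            raise ValueError("k-fold schemes need k >= 2")

    @staticmethod
    def for_sample_size(n: int, k: int = 5, seed: int = 0,
                        spatial: bool = False) -> "CVScheme":
        if n < SMALL_SAMPLE_CUTOFF:
            return CVScheme("jackknife", k=n, seed=seed)
        return CVScheme("kfold_spatial" if spatial else "kfold_random", k=k, seed=seed)


def make_folds(points: np.ndarray, scheme: CVScheme
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition point indices into (train, test) folds.

    Random mode: seeded shuffle, fold sizes differing by at most one.
    Jackknife: one fold per point.  Spatial mode: seeded k-means on the
    coordinates (best of 10 restarts); each cluster is one test fold.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two points to make folds")
    if scheme.mode == "jackknife":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    if scheme.k > n:
        raise ValueError(f"k={scheme.k} exceeds n={n}")
    if scheme.mode == "kfold_random":
        rng = np.random.default_rng(scheme.seed)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, scheme.k)
        return [(np.setdiff1d(np.arange(n), c), np.sort(c)) for c in chunks]
    # spatial: k-means clusters become folds
    km = KMeans(n_clusters=scheme.k, n_init=10, random_state=scheme.seed)
    labels = km.fit_predict(pts)
    folds = []
    for c in range(scheme.k):
        test = np.flatnonzero(labels == c)
        if len(test) == 0:  # pragma: no cover - k-means with k<=n fills clusters
            continue
        folds.append((np.flatnonzero(labels != c), test))
    return folds


def inter_fold_distances(points: np.ndarray,
                         folds: list[tuple[np.ndarray, np.ndarray]]
                         ) -> tuple[float, float]:
    """Mean and minimum train-test point distance across folds (metres)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    means, mins = [], []
    for train, test in folds:
        d = np.sqrt(((pts[test][:, None, :] - pts[train][None, :, :]) ** 2).sum(-1))
        means.append(d.mean())
        mins.append(d.min())
    return float(np.mean(means)), float(np.min(mins))


def threshold_max_sens_spec(presence_scores: np.ndarray,
                            background_scores: np.ndarray) -> float:
    """Occupancy threshold maximising test sensitivity + specificity.

    Candidates are the unique observed scores; sensitivity counts
    presences at or above the threshold, specificity background strictly
    below it.  Ties between maximising thresholds resolve to the largest
    one (the conservative choice: smallest predicted-suitable area).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("empty score list")
    cands = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= cands[:, None]).mean(axis=1)
    spec = (b[None, :] < cands[:, None]).mean(axis=1)
    total = sens + spec
    if len(cands) == 1:
        warnings.warn("degenerate scores: single threshold candidate")
    best = np.flatnonzero(total >= total.max() - 1e-12)[-1]
    return float(cands[best])


def omission_test(test_presence_scores: np.ndarray, threshold: float,
                  suitable_fraction: float) -> tuple[float, float]:
    """Extrinsic omission rate and one-sided binomial p-value.

    Under the null, each test presence lands in the predicted-suitable
    area with probability ``suitable_fraction``; the p-value is
    P(Binomial(n, a) >= s) for s test presences scoring at or above the
    threshold — small when omission is lower than chance placement.
    """
    scores = np.asarray(test_presence_scores, dtype=float)
    n = len(scores)
    if n < 1:
        raise ValueError("need at least one test presence")
    a = float(suitable_fraction)
    if not 0.0 < a < 1.0:
        raise ValueError("suitable_fraction must lie strictly between 0 and 1")
    s = int((scores >= threshold).sum())
    omission = 1.0 - s / n
    p = float(binom.sf(s - 1, n, a))
    return omission, p


@dataclass
class CorrelogramResult:
    bins_km: list[tuple[float, float]]
    I: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    n_pairs: np.ndarray
    rsac_lag_km: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_km": [b[0] for b in self.bins_km],
            "bin_hi_km": [b[1] for b in self.bins_km],
            "n_pairs": self.n_pairs,
            "morans_I": self.I,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
        })


def morans_correlogram(residuals: np.ndarray, coords: np.ndarray,
                       bin_edges_km: np.ndarray | None = None,
                       n_perm: int = 9999, seed: int = 0,
                       correction: str = "bonferroni",
                       alpha: float = 0.05) -> CorrelogramResult:
    """Moran's I per distance band with Monte-Carlo permutation p-values.

    Residuals (e.g. 1 - predicted HSI at the presence points) are tested
    for spatial autocorrelation in contiguous distance bands (default:
    1 km bands out to half the maximum pairwise distance).  Significance
    uses ``n_perm`` seeded permutations of the residuals over the
    locations, two-sided on |I|, corrected across bands (Bonferroni by
    default, Holm optional).  ``rsac_lag_km`` is the upper edge of the
    farthest band in the initial contiguous run of significant positive
    autocorrelation, or None when the first band is not significant.
    """
    z = np.asarray(residuals, dtype=float)
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 points")
    z = z - z.mean()
    denom = float((z ** 2).sum())
    if denom <= 0:
        raise ValueError("zero-variance residuals: Moran's I undefined")

    d_km = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)) / 1000.0
    np.fill_diagonal(d_km, np.nan)
    if bin_edges_km is None:
        dmax = np.nanmax(d_km)
        upper = max(1.0, np.ceil(dmax / 2.0))
        bin_edges_km = np.arange(0.0, upper + 1.0)
    edges = np.asarray(bin_edges_km, dtype=float)
    bins = list(zip(edges[:-1], edges[1:]))

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)

    I = np.full(len(bins), np.nan)
    p_raw = np.full(len(bins), np.nan)
    n_pairs = np.zeros(len(bins), dtype=int)
    with np.errstate(invalid="ignore"):
        for bi, (lo, hi) in enumerate(bins):
            W = (d_km > lo) & (d_km <= hi) if lo > 0 else (d_km <= hi)
            W = W & ~np.isnan(d_km)
            s0 = W.sum()
            n_pairs[bi] = int(s0)
            if s0 == 0:
                continue
            obs = (n / s0) * float(z @ W @ z) / denom
            I[bi] = obs
            cross = np.einsum("pi,ij,pj->p", perms, W.astype(float), perms)
            I_star = (n / s0) * cross / denom
            p_raw[bi] = (1 + int((np.abs(I_star) >= abs(obs) - 1e-12).sum())) / (1 + n_perm)

    defined = ~np.isnan(p_raw)
    m = int(defined.sum())
    p_corr = np.full(len(bins), np.nan)
    if correction == "bonferroni":
        p_corr[defined] = np.minimum(1.0, p_raw[defined] * m)
    elif correction == "holm":
        order = np.argsort(p_raw[defined])
        vals = p_raw[defined][order] * (m - np.arange(m))
        vals = np.minimum(1.0, np.maximum.accumulate(vals))
        out = np.empty(m)
        out[order] = vals
        p_corr[defined] = out
    elif correction == "none":
        p_corr[defined] = p_raw[defined]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    rsac = None
    for bi in range(len(bins)):
        ok = defined[bi] and p_corr[bi] <= alpha and I[bi] > 0
        if not ok:
            break
        rsac = bins[bi][1]
    return CorrelogramResult(bins, I, p_raw, p_corr, n_pairs, rsac)


@dataclass
class EvaluationReport:
    folds: pd.DataFrame
    threshold: float
    suitable_fraction: float
    omission_rate: float
    p_omission: float
    correlogram: CorrelogramResult | None = None
    scheme: CVScheme | None = None
    fold_distances: tuple[float, float] | None = None

    @property
    def train_auc(self) -> float:
        return float(self.folds["train_auc"].mean())

    @property
    def test_auc(self) -> float:
        return float(self.folds["test_auc"].mean())

    @property
    def test_gain(self) -> float:
        return float(self.folds["test_gain"].mean())

    def summary(self) -> dict[str, float]:
        f = self.folds
        return {
            "n_folds": float(len(f)),
            "train_auc_mean": float(f["train_auc"].mean()),
            "train_auc_sd": float(f["train_auc"].std(ddof=1)) if len(f) > 1 else 0.0,
            "test_auc_mean": float(f["test_auc"].mean()),
            "test_auc_sd": float(f["test_auc"].std(ddof=1)) if len(f) > 1 else 0.0,
            "test_gain_mean": float(f["test_gain"].mean()),
            "threshold": self.threshold,
            "suitable_fraction": self.suitable_fraction,
            "omission_rate": self.omission_rate,
            "p_omission": self.p_omission,
        }


def evaluate_model(presences: pd.DataFrame, pseudoabsences: pd.DataFrame,
                   presence_xy: np.ndarray, scheme: CVScheme,
                   categorical: set[str] = frozenset(),
                   spec: FeatureSpec = FeatureSpec(), beta_mult: float = 2.0,
                   threshold_on: str = "auto") -> EvaluationReport:
    """Cross-validated fit and evaluation of one variable set.

    ``presences``/``pseudoabsences`` are variable tables over the points;
    the background of every fold is the pseudoabsence table plus the
    training presences.  Per fold the report records train/test AUC
    (presences scored against the pseudoabsences), unpenalised test gain,
    the max-sens+spec HSI threshold, the fraction of pseudoabsence cells
    predicted suitable, and the omission of test presences; the pooled
    binomial omission test combines folds.

    ``threshold_on``: "test" thresholds on the held-out scores, "train"
    on the training scores; "auto" uses test scores except under
    jackknife, whose single-point test folds are degenerate.
    """
    if threshold_on == "auto":
        threshold_on = "train" if scheme.mode == "jackknife" else "test"
    folds = make_folds(presence_xy, scheme)
    rows = []
    pooled_s = 0
    pooled_n = 0
    for fi, (train, test) in enumerate(folds):
        train_df = presences.iloc[train]
        test_df = presences.iloc[test]
        background = pd.concat([pseudoabsences, train_df], ignore_index=True)
        model = fit_sdm(train_df, background, categorical=categorical, spec=spec,
                        beta_mult=beta_mult)
        pa_F = model.builder.transform(pseudoabsences)
        pa_logit = predict(model, pa_F, "logistic")
        tr_logit = predict(model, model.builder.transform(train_df), "logistic")
        te_F = model.builder.transform(test_df)
        te_logit = predict(model, te_F, "logistic")
        thr_scores = tr_logit if threshold_on == "train" else te_logit
        thr = threshold_max_sens_spec(thr_scores, pa_logit)
        a = float(np.clip((pa_logit >= thr).mean(), 1e-9, 1 - 1e-9))
        omission, p_om = omission_test(te_logit, thr, a)
        rows.append({
            "fold": fi,
            "n_train": len(train), "n_test": len(test),
            "train_auc": auc(tr_logit, pa_logit),
            "test_auc": auc(te_logit, pa_logit),
            "test_gain": gain(model, te_F, penalised=False),
            "threshold": thr,
            "suitable_fraction": a,
            "omission_rate": omission,
            "p_omission": p_om,
        })
        pooled_s += int((te_logit >= thr).sum())
        pooled_n += len(test)
    fold_df = pd.DataFrame(rows)
    a_mean = float(np.clip(fold_df["suitable_fraction"].mean(), 1e-9, 1 - 1e-9))
    p_pooled = float(binom.sf(pooled_s - 1, pooled_n, a_mean))
    dists = inter_fold_distances(presence_xy, folds)
    return EvaluationReport(
        folds=fold_df,
        threshold=float(fold_df["threshold"].mean()),
        suitable_fraction=a_mean,
        omission_rate=1.0 - pooled_s / pooled_n,
        p_omission=p_pooled,
        scheme=scheme,
        fold_distances=dists,
    )
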