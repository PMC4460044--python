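"""Cross-validation folds, thresholding, omission tests and Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from maxscale.validation import (CVScheme, evaluate_model, inter_fold_distances,
                                 make_folds, morans_correlogram, omission_test,
                                 threshold_max_sens_spec)


# ---------------------------------------------------------------------------
# folds

def test_folds_partition_property(rng):
    pts = rng.random((37, 2)) * 1000
    for scheme in (CVScheme("kfold_random", 5, 1), CVScheme("jackknife"),
                   CVScheme("kfold_spatial", 5, 1)):
        folds = make_folds(pts, scheme)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(37))
        for train, test in folds:
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 37


def test_jackknife_below_cutoff():
    pts = np.random.default_rng(0).random((23, 2))
    scheme = CVScheme.for_sample_size(23)
    assert scheme.mode == "jackknife"
    folds = make_folds(pts, scheme)
    assert len(folds) == 23 and all(len(t) == 1 for _, t in folds)
    assert CVScheme.for_sample_size(25).mode == "kfold_random"


def test_random_fold_sizes_balanced(rng):
    folds = make_folds(rng.random((23, 2)), CVScheme("kfold_random", 5, 3))
    sizes = sorted(len(t) for _, t in folds)
    assert max(sizes) - min(sizes) <= 1


def test_spatial_folds_separate_distant_clouds(rng):
    wins = 0
    for seed in range(20):
        g = np.random.default_rng(seed)
        pts = np.vstack([g.normal(0, 2000, (20, 2)),
                         g.normal(30000, 2000, (20, 2))])
        d_rand, _ = inter_fold_distances(pts, make_folds(pts, CVScheme("kfold_random", 2, seed)))
        d_spat, _ = inter_fold_distances(pts, make_folds(pts, CVScheme("kfold_spatial", 2, seed)))
        wins += d_spat > d_rand
    assert wins >= 18


def test_k_larger_than_n_errors(rng):
    with pytest.raises(ValueError):
        make_folds(rng.random((3, 2)), CVScheme("kfold_random", 5, 0))


# ---------------------------------------------------------------------------
# threshold rule

def brute_threshold(p, b):
    cands = sorted(set(list(p) + list(b)))
    best_t, best_v = None, -1.0
    for t in cands:  # scanning upward keeps the largest tied maximiser
        v = np.mean(np.asarray(p) >= t) + np.mean(np.asarray(b) < t)
        if v > best_v - 1e-12:
            best_t, best_v = t, max(v, best_v)
    return best_t


def test_threshold_worked_example():
    # sens+spec peaks at 5/3, attained at both 0.3 and 0.6; the tie
    # resolves to the larger (more conservative) threshold
    t = threshold_max_sens_spec([0.8, 0.6, 0.3], [0.5, 0.2, 0.1])
    assert t == pytest.approx(0.6)


def test_threshold_separation_and_degenerate():
    assert threshold_max_sens_spec([0.9, 0.8], [0.2, 0.1]) == pytest.approx(0.8)
    with pytest.warns(UserWarning):
        t = threshold_max_sens_spec([0.4, 0.4], [0.4])
    assert t == pytest.approx(0.4)


def test_threshold_matches_exhaustive_scan(rng):
    for _ in range(100):
        p = rng.choice(np.round(np.linspace(0, 1, 21), 3), size=rng.integers(1, 25))
        b = rng.choice(np.round(np.linspace(0, 1, 21), 3), size=rng.integers(1, 25))
        assert threshold_max_sens_spec(p, b) == pytest.approx(brute_threshold(p, b))


# ---------------------------------------------------------------------------
# omission binomial test

def test_omission_closed_forms():
    om, p = omission_test([0.9] * 5, 0.5, 0.5)
    assert om == 0.0 and p == pytest.approx(0.03125)
    om0, p0 = omission_test([0.1, 0.2], 0.5, 0.3)
    assert om0 == 1.0 and p0 == pytest.approx(1.0)


def test_omission_binomial_tail_summation():
    # a=0.3, n=10, s=8: tail by direct summation
    scores = [0.9] * 8 + [0.1] * 2
    om, p = omission_test(scores, 0.5, 0.3)
    want = sum(comb(10, k) * 0.3 ** k * 0.7 ** (10 - k) for k in (8, 9, 10))
    assert om == pytest.approx(0.2)
    assert p == pytest.approx(want, abs=1e-12)


def test_omission_random_cross_check(rng):
    for _ in range(50):
        n = int(rng.integers(1, 30))
        a = float(rng.uniform(0.05, 0.95))
        s = int(rng.integers(0, n + 1))
        scores = [1.0] * s + [0.0] * (n - s)
        _, p = omission_test(scores, 0.5, a)
        want = sum(comb(n, k) * a ** k * (1 - a) ** (n - k) for k in range(s, n + 1))
        assert p == pytest.approx(want, abs=1e-12)
    with pytest.raises(ValueError):
        omission_test([1.0], 0.5, 1.0)


# ---------------------------------------------------------------------------
# Moran's correlogram

def brute_morans_I(z, coords_km, lo, hi):
    z = np.asarray(z, float)
    z = z - z.mean()
    n = len(z)
    num = s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(coords_km[i] - coords_km[j]))
            if (d > lo or lo == 0) and d <= hi:
                num += z[i] * z[j]
                s0 += 1
    return (n / s0) * num / (z ** 2).sum()


def test_morans_collinear_example():
    # neighbour pairs (1,2),(2,3),(3,4): symmetric double-sum = 2, S0 = 6,
    # so I = (4/6) * 2 / 4 = 1/3; agrees with the brute-force double sum
    coords = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0], [3000.0, 0.0]])
    z = np.array([1.0, 1.0, -1.0, -1.0])
    res = morans_correlogram(z, coords, bin_edges_km=[0.0, 1.5], n_perm=99, seed=0)
    assert res.I[0] == pytest.approx(1.0 / 3.0)
    assert res.I[0] == pytest.approx(brute_morans_I(z, coords / 1000.0, 0.0, 1.5))
    assert res.n_pairs[0] == 6  # 3 undirected pairs, symmetric weights


def test_morans_matches_bruteforce(rng):
    for _ in range(15):
        n = int(rng.integers(5, 15))
        coords = rng.random((n, 2)) * 5000
        z = rng.normal(size=n)
        res = morans_correlogram(z, coords, bin_edges_km=[0.0, 2.0, 4.0, 8.0],
                                 n_perm=9, seed=1)
        for bi, (lo, hi) in enumerate(res.bins_km):
            if res.n_pairs[bi]:
                want = brute_morans_I(z, coords / 1000.0, lo, hi)
                assert res.I[bi] == pytest.approx(want, abs=1e-9)


def test_morans_shuffled_field_centres_on_expected_value(rng):
    n = 30
    coords = rng.random((n, 2)) * 3000
    vals = []
    for s in range(200):
        z = np.random.default_rng(s).normal(size=n)
        res = morans_correlogram(z, coords, bin_edges_km=[0.0, 1.5], n_perm=9, seed=0)
        vals.append(res.I[0])
    assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=0.05)
    assert np.min(vals) > -1.2 and np.max(vals) < 1.2


def test_morans_null_p_uniform(rng):
    # under a random field the permutation p-values are roughly uniform
    # (band strictly inside the point cloud so W is permutation-sensitive)
    coords = rng.random((25, 2)) * 4000
    ps = []
    for s in range(60):
        z = np.random.default_rng(1000 + s).normal(size=25)
        res = morans_correlogram(z, coords, bin_edges_km=[0.0, 1.5],
                                 n_perm=199, seed=s, correction="none")
        ps.append(res.p_corrected[0])
    from scipy.stats import kstest
    assert kstest(ps, "uniform").pvalue > 0.01


def test_morans_errors_and_rsac_lag():
    n = 40
    coords = np.arange(n, dtype=float).reshape(-1, 1) * np.array([[500.0, 0.0]])
    with pytest.raises(ValueError):
        morans_correlogram(np.ones(n), coords, n_perm=9, seed=0)
    # strong spatial gradient -> significant positive I in the first band(s)
    z = np.arange(n, dtype=float)
    res = morans_correlogram(z, coords, bin_edges_km=[0.0, 2.0, 4.0, 8.0],
                             n_perm=999, seed=2)
    assert res.rsac_lag_km is not None and res.rsac_lag_km >= 2.0


def test_morans_determinism(rng):
    coords = rng.random((20, 2)) * 5000
    z = rng.normal(size=20)
    r1 = morans_correlogram(z, coords, n_perm=99, seed=5)
    r2 = morans_correlogram(z, coords, n_perm=99, seed=5)
    np.testing.assert_array_equal(r1.p_raw, r2.p_raw)


# ---------------------------------------------------------------------------
# evaluate_model plumbing

def test_evaluate_model_report_contract(rng):
    n = 40
    bg = pd.DataFrame({"a": rng.random(300)})
    pres = pd.DataFrame({"a": np.clip(rng.normal(0.8, 0.1, n), 0, 1)})
    xy = rng.random((n, 2)) * 10000
    rep = evaluate_model(pres, bg, xy, CVScheme("kfold_random", 5, 0))
    assert len(rep.folds) == 5
    assert 0.0 <= rep.omission_rate <= 1.0
    assert 0.0 < rep.suitable_fraction < 1.0
    assert rep.test_auc > 0.6  # strong separation by construction
    s = rep.summary()
    assert {"test_auc_mean", "omission_rate", "threshold"} <= set(s)
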