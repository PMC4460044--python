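"""Maximum-entropy estimator: feature building, optimiser correctness
against independent 1-D/grid oracles, prediction, gain, AUC, importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from maxscale.maxent import (FeatureBuilder, FeatureSpec, auc,
                             auto_feature_classes, fit_maxent, fit_sdm, gain,
                             permutation_importance, predict, predict_vars)


def test_feature_scaling_endpoints():
    bg = pd.DataFrame({"v": [2.0, 4.0, 10.0]})
    b = FeatureBuilder(bg, spec=FeatureSpec(classes=frozenset({"linear"})))
    F = b.transform(pd.DataFrame({"v": [10.0, 2.0, 6.0]}))
    np.testing.assert_allclose(F[:, 0], [1.0, 0.0, 0.5])


def test_hinge_below_knot_is_zero():
    bg = pd.DataFrame({"v": np.linspace(0, 1, 11)})
    b = FeatureBuilder(bg, spec=FeatureSpec(classes=frozenset({"hinge"}), knots=3))
    F = b.transform(pd.DataFrame({"v": [0.1]}))
    # knots at 0.25, 0.5, 0.75: value below every knot -> all hinges 0
    np.testing.assert_allclose(F, 0.0)


@pytest.mark.parametrize("n,expect", [
    (5, {"linear"}),
    (12, {"linear", "quadratic"}),
    (50, {"linear", "quadratic", "hinge"}),
    (200, {"linear", "quadratic", "hinge", "product", "threshold"}),
])
def test_auto_feature_table(n, expect):
    assert auto_feature_classes(n) - {"categorical"} == expect


def test_categorical_indicators():
    bg = pd.DataFrame({"c": [1.0, 2.0, 2.0, 5.0]})
    b = FeatureBuilder(bg, categorical={"c"},
                       spec=FeatureSpec(classes=frozenset({"categorical"})))
    F = b.transform(pd.DataFrame({"c": [2.0]}))
    np.testing.assert_array_equal(F, [[0.0, 1.0, 0.0]])


# ---------------------------------------------------------------------------
# optimiser

def test_fit_matches_golden_section_oracle():
    B = np.array([[1.0], [1.0], [0.0], [0.0]])
    P = np.array([[1.0], [1.0]])

    def neg_objective(lam):
        return -(lam - logsumexp(B[:, 0] * lam) - 0.05 * abs(lam))

    oracle = minimize_scalar(neg_objective, bounds=(-25, 25), method="bounded",
                             options={"xatol": 1e-12})
    model = fit_maxent(P, B, beta=0.05)
    assert model.weights[0] == pytest.approx(oracle.x, abs=1e-4)
    raw = predict(model, B, "raw")
    assert raw.sum() == pytest.approx(1.0, abs=1e-9)
    lam = oracle.x
    expect = np.exp(B[:, 0] * lam - logsumexp(B[:, 0] * lam))
    np.testing.assert_allclose(raw, expect, atol=1e-6)


def test_fit_matches_dense_grid_oracle_two_features(rng):
    B = rng.random((30, 2))
    P = B[rng.choice(30, 8, replace=False)]
    beta = 0.02
    model = fit_maxent(P, B, beta=beta)

    def objective(l1, l2):
        lam = np.array([l1, l2])
        u = B @ lam
        return P.mean(axis=0) @ lam - logsumexp(u) - beta * (abs(l1) + abs(l2))

    grid = np.linspace(-10, 10, 161)
    vals = np.array([[objective(a, b) for b in grid] for a in grid])
    best = np.unravel_index(vals.argmax(), vals.shape)
    fitted = objective(*model.weights)
    assert fitted >= vals[best] - 1e-3  # optimiser at least as good as the grid


def test_empty_and_constant_features_give_uniform():
    m = fit_maxent(np.empty((3, 0)), np.empty((10, 0)))
    raw = predict(m, np.empty((10, 0)), "raw")
    np.testing.assert_allclose(raw, 0.1)
    assert gain(m, np.empty((3, 0))) == pytest.approx(0.0)
    # constant feature over background: constraint already satisfied
    B = np.full((10, 1), 0.7)
    m2 = fit_maxent(np.full((3, 1), 0.7), B, beta=0.01)
    np.testing.assert_allclose(predict(m2, B, "raw"), 0.1, atol=1e-9)


def test_unpenalised_fit_matches_presence_mean(rng):
    # with beta=0 and one binary feature, E_raw[f] converges to presence mean
    f_bg = np.array([1.0] * 4 + [0.0] * 6)[:, None]
    pres = np.array([[1.0], [1.0], [1.0], [0.0]])
    m = fit_maxent(pres, f_bg, beta=0.0, max_iter=5000)
    raw = predict(m, f_bg, "raw")
    assert raw @ f_bg[:, 0] == pytest.approx(0.75, abs=1e-4)


def test_uniform_four_cell_logistic_is_half():
    m = fit_maxent(np.empty((2, 0)), np.empty((4, 0)))
    assert m.entropy == pytest.approx(np.log(4))
    np.testing.assert_allclose(predict(m, np.empty((4, 0)), "logistic"), 0.5)


def test_logistic_monotone_in_raw(rng):
    B = rng.random((40, 2))
    m = fit_maxent(B[:5], B, beta=0.05)
    raw = predict(m, B, "raw")
    logi = predict(m, B, "logistic")
    order = np.argsort(raw)
    assert np.all(np.diff(logi[order]) >= -1e-15)
    assert np.all((logi > 0) & (logi < 1))


# ---------------------------------------------------------------------------
# gain and AUC

def test_gain_direct_formula():
    # all presence mass on 2 of 10 cells, raw 0.5 each -> gain = ln 5
    B = np.array([[1.0]] * 2 + [[0.0]] * 8)
    m = fit_maxent(np.array([[1.0]]), B, beta=0.0, max_iter=5000)
    g = gain(m, np.array([[1.0]]))
    assert g == pytest.approx(np.log(5), abs=2e-3)


def test_penalised_gain_not_larger(rng):
    B = rng.random((30, 2))
    m = fit_maxent(B[:6], B, beta=0.1)
    P = B[:6]
    assert gain(m, P, penalised=True) <= gain(m, P, penalised=False) + 1e-12


def test_auc_examples_and_pair_oracle(rng):
    assert auc([1.0, 0.9], [0.1, 0.2]) == 1.0
    assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5
    assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)
    for _ in range(20):
        p = rng.choice(np.linspace(0, 1, 7), size=rng.integers(1, 12))
        b = rng.choice(np.linspace(0, 1, 7), size=rng.integers(1, 12))
        pairs = [(1.0 if x > y else 0.5 if x == y else 0.0) for x in p for y in b]
        assert auc(p, b) == pytest.approx(np.mean(pairs), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=20),
       st.lists(st.floats(0, 1, width=32), min_size=1, max_size=20),
       st.floats(0.1, 5.0))
def test_auc_invariant_under_monotone_transform(p, b, k):
    f = lambda x: np.expm1(k * np.asarray(x, dtype=float))  # strictly increasing
    assert auc(p, b) == pytest.approx(auc(f(p), f(b)), abs=1e-12)


def test_training_gain_nondecreasing_with_features(rng):
    bg = pd.DataFrame({"a": rng.random(50), "b": rng.random(50)})
    pres = bg.iloc[:10]
    g = {}
    for cols in (["a"], ["a", "b"]):
        m = fit_sdm(pres[cols], bg[cols],
                    spec=FeatureSpec(classes=frozenset({"linear"})), beta_mult=0.0)
        m2 = fit_maxent(m.builder.transform(pres[cols]),
                        m.builder.transform(bg[cols]), beta=0.0, max_iter=5000)
        g[tuple(cols)] = gain(m2, m.builder.transform(pres[cols]))
    assert g[("a", "b")] >= g[("a",)] - 1e-6


# ---------------------------------------------------------------------------
# permutation importance

def test_importance_single_variable_and_determinism(rng):
    bg = pd.DataFrame({"a": rng.random(80)})
    pres = bg.iloc[np.argsort(bg["a"])[-15:]]
    m = fit_sdm(pres, bg, spec=FeatureSpec(classes=frozenset({"linear"})))
    imp = permutation_importance(m, pres, bg, seed=4)
    assert imp == {"a": 100.0}
    bg2 = bg.assign(b=rng.random(80))
    m2 = fit_sdm(pres.assign(b=rng.random(15)), bg2,
                 spec=FeatureSpec(classes=frozenset({"linear"})))
    i1 = permutation_importance(m2, pres.assign(b=1.0), bg2, seed=9)
    i2 = permutation_importance(m2, pres.assign(b=1.0), bg2, seed=9)
    assert i1 == i2
    assert sum(i1.values()) == pytest.approx(100.0)


def test_predict_vars_roundtrip(rng):
    bg = pd.DataFrame({"a": rng.random(60), "b": rng.random(60)})
    pres = bg.iloc[:12]
    m = fit_sdm(pres, bg)
    direct = predict(m, m.builder.transform(bg), "logistic")
    np.testing.assert_array_equal(predict_vars(m, bg, "logistic"), direct)
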