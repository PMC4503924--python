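"""Bray-Curtis, Mantel permutation test, OLS, observed:expected ratios."""

import numpy as np
import pandas as pd
import pytest

from ampflow.stats import (
    CycleDesign,
    DistanceMatrix,
    bray_curtis,
    bray_curtis_matrix,
    cycle_distance_matrix,
    mantel,
    obs_exp_ratios,
    ols_fit,
)

UNEVEN = np.array([76.0, 18.0, 5.0, 0.7, 0.09])


def test_bray_curtis_basics():
    assert bray_curtis([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0)  # same profile after normalizing
    assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)  # disjoint supports
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [1, 1])


def test_bray_curtis_uneven_vs_even_closed_form():
    even = np.full(5, 0.2)
    expected = float(np.abs(UNEVEN / UNEVEN.sum() - even).sum() / 2)
    assert bray_curtis(UNEVEN, even) == pytest.approx(expected)


def test_bray_curtis_symmetry_and_bounds(rng):
    for _ in range(20):
        x = rng.random(6) + 1e-9
        y = rng.random(6) + 1e-9
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(y, x))
    assert bray_curtis(x, x) == pytest.approx(0.0)


def _designs():
    combos = [(10, 20), (15, 15), (20, 10), (25, 5), (25, 10), (30, 10), (30, 5), (35, 10), (35, 5)]
    return [CycleDesign(f"lib{i}", c1, c2) for i, (c1, c2) in enumerate(combos)]


def test_cycle_distance_matrix():
    designs = _designs()
    dm = cycle_distance_matrix(designs)
    assert dm.values[0, 1] == 0  # 10:20 and 15:15 both total 30
    assert dm.values[0, 4] == 5  # |30 - 35|
    assert np.all(np.diag(dm.values) == 0)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))  # nonzero diagonal


def test_mantel_self_correlation_is_one(rng):
    v = np.abs(rng.random((6, 6)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    dm = DistanceMatrix(list("abcdef"), v)
    res = mantel(dm, dm, n_permutations=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 100, abs=0.05)


def test_mantel_r_equals_triangle_pearson(rng):
    for _ in range(10):
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((6, 6))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        d1, d2 = DistanceMatrix(list("abcdef"), a), DistanceMatrix(list("abcdef"), b)
        res = mantel(d1, d2, n_permutations=9, seed=1)
        i, j = np.tril_indices(6, k=-1)
        want = np.corrcoef(a[i, j], b[i, j])[0, 1]
        assert res.r == pytest.approx(want)


def test_mantel_agrees_with_skbio(rng):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    a = rng.random((7, 7))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = a + rng.random((7, 7)) * 0.3
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    labels = list("abcdefg")
    ours = mantel(DistanceMatrix(labels, a), DistanceMatrix(labels, b), 999, seed=3)
    ref_r, ref_p, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(a, labels),
        skbio_distance.DistanceMatrix(b, labels),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    assert ours.r == pytest.approx(float(ref_r), abs=1e-12)
    assert ours.p == pytest.approx(float(ref_p), abs=0.02)  # both permutation estimates


def test_mantel_constant_triangle_is_fatal():
    z = np.zeros((4, 4))
    with pytest.raises(ValueError):
        mantel(DistanceMatrix(list("abcd"), z), DistanceMatrix(list("abcd"), z), 99)


def test_ols_exact_line():
    x = np.arange(10, dtype=float)
    fit = ols_fit(2 * x, pd.DataFrame({"x": x}))
    assert fit.params["x"] == pytest.approx(2.0)
    assert fit.rsquared == pytest.approx(1.0)
    assert np.allclose(fit.residuals, 0)


def test_ols_matches_normal_equations_oracle(rng):
    for _ in range(10):
        X = rng.random((20, 3))
        y = rng.random(20)
        design = pd.DataFrame(X, columns=["a", "b", "c"])
        fit = ols_fit(y, design)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta)
        # classical SEs from (X'X)^-1 sigma^2
        resid = y - Xd @ beta
        sigma2 = resid @ resid / (20 - 4)
        se = np.sqrt(np.diag(np.linalg.inv(Xd.T @ Xd)) * sigma2)
        assert np.allclose(fit.bse.to_numpy(), se)
        assert fit.df_resid == 16


def test_ols_simple_regression_closed_form(rng):
    x = rng.random(30)
    y = 1.5 * x + rng.normal(0, 0.1, 30)
    fit = ols_fit(y, pd.DataFrame({"x": x}))
    want = float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())
    assert fit.params["x"] == pytest.approx(want)
    assert fit.rsquared_adj <= fit.rsquared


def test_ols_categorical_and_anova(rng):
    group = np.repeat(["a", "b", "c"], 10)
    x = rng.random(30)
    y = x + np.where(group == "b", 1.0, 0.0) + rng.normal(0, 0.1, 30)
    fit = ols_fit(y, pd.DataFrame({"x": x, "grp": group}))
    assert fit.params["C(grp)[T.b]"] == pytest.approx(1.0, abs=0.2)
    assert fit.anova_typeI is not None and "C(grp)" in fit.anova_typeI.index


def test_ols_rank_deficient_raises(rng):
    x = rng.random(15)
    with pytest.raises(ValueError, match="collinear"):
        ols_fit(rng.random(15), pd.DataFrame({"x": x, "x2": 2 * x}))


def test_obs_exp_ratios():
    counts = pd.Series({"a": 2, "b": 1, "c": 1})
    mult = pd.Series({"a": 2, "b": 1, "c": 1})
    ratios, _ = obs_exp_ratios(counts, mult)
    assert np.allclose(ratios, 1.0)  # expected fractions 0.5/0.25/0.25

    equal = pd.Series({"a": 5, "b": 5})
    ratios, _ = obs_exp_ratios(equal, pd.Series({"a": 1, "b": 1}))
    assert np.allclose(ratios, 1.0)

    with pytest.raises(ValueError):
        obs_exp_ratios(pd.Series({"a": 0}), pd.Series({"a": 1}))
    with pytest.raises(ValueError):
        obs_exp_ratios(counts, pd.Series({"a": 0.5, "b": 1, "c": 1}))


def test_obs_exp_design_passthrough():
    counts = pd.Series({"a": 3, "b": 1})
    mult = pd.Series({"a": 1, "b": 1})
    design = pd.DataFrame({"preparer": ["p1", "p2"], "amplicon_len": [300, 700]}, index=["a", "b"])
    ratios, aligned = obs_exp_ratios(counts, mult, design)
    assert ratios["a"] == pytest.approx(1.5)
    assert list(aligned.index) == ["a", "b"]


def test_bray_curtis_matrix_labels(rng):
    profiles = pd.DataFrame(rng.random((5, 3)) + 0.01, columns=["x", "y", "z"])
    dm = bray_curtis_matrix(profiles)
    assert dm.labels == ["x", "y", "z"]
    assert dm.values[0, 1] == pytest.approx(bray_curtis(profiles["x"], profiles["y"]))
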