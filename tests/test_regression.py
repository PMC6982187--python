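"""Estimator suite: screening, VIF, OLS/SAR/GWR correctness, comparison
rule, and coefficient standardization."""

import numpy as np
import pandas as pd
import pytest

from revaccess.regression import (GWR, Design, OLSModel, SpatialLag, compare_models,
                                  fit_gwr, fit_ols, fit_sar, pearson_screen,
                                  standardize_coefficients, vif)
from revaccess.spatial import inverse_distance_weights
from revaccess.synthetic import clustered_coords, plant_sar_outcome


def _design(y, X, names, coords=None):
    return Design(ids=list(range(len(y))), y=y, X=X, names=names, coords=coords)


# ---------------------------------------------------------------------------
# screening


def test_screen_retains_true_predictor_and_controls_false_positives():
    keep_x1 = 0
    keep_x2 = 0
    for seed in range(200):
        rg = np.random.default_rng(seed)
        x1 = rg.standard_normal(200)
        x2 = rg.standard_normal(200)
        y = x1 + 0.1 * rg.standard_normal(200)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        kept = pearson_screen(df, "y", ["x1", "x2"], alpha=0.05)
        keep_x1 += "x1" in kept
        keep_x2 += "x2" in kept
    assert keep_x1 == 200
    assert keep_x2 / 200 < 0.12  # nominal 5% false-positive rate


def test_screen_perfect_correlation_retained():
    x = np.arange(10.0)
    df = pd.DataFrame({"y": x, "x": x})
    assert pearson_screen(df, "y", ["x"]) == ["x"]


def test_screen_constant_covariate_warns_and_excludes():
    df = pd.DataFrame({"y": np.arange(8.0), "c": np.ones(8)})
    with pytest.warns(UserWarning, match="variance"):
        assert pearson_screen(df, "y", ["c"]) == []


def test_vif_closed_form_for_correlated_pair(rng):
    n = 5000
    r = 0.8
    x1 = rng.standard_normal(n)
    x2 = r * x1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
    df = pd.DataFrame({"x1": x1, "x2": x2})
    v = vif(df, ["x1", "x2"])
    r_emp = np.corrcoef(x1, x2)[0, 1]
    assert v["x1"] == pytest.approx(1.0 / (1.0 - r_emp ** 2), rel=1e-9)


def test_vif_orthogonal_is_one():
    x1 = np.tile([1.0, -1.0], 8)
    x2 = np.repeat([1.0, -1.0], 8)
    v = vif(pd.DataFrame({"x1": x1, "x2": x2}), ["x1", "x2"])
    assert v["x1"] == pytest.approx(1.0, abs=1e-12)
    assert v["x2"] == pytest.approx(1.0, abs=1e-12)


def test_vif_duplicate_covariate_is_infinite(rng):
    x = rng.standard_normal(30)
    v = vif(pd.DataFrame({"a": x, "b": x}), ["a", "b"])
    assert np.isinf(v["a"]) and np.isinf(v["b"])


# ---------------------------------------------------------------------------
# OLS


def test_ols_exact_line():
    # noiseless points on y = 2x + 1 recover the line exactly with R^2 = 1
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    X = np.column_stack([np.ones(5), x])
    f = fit_ols(_design(2 * x + 1, X, ["intercept", "x"]))
    np.testing.assert_allclose(f.params, [1.0, 2.0], atol=1e-10)
    assert f.r2 == pytest.approx(1.0)


def test_ols_matches_normal_equations(rng):
    X = np.column_stack([np.ones(6), rng.standard_normal(6)])
    y = rng.standard_normal(6)
    f = fit_ols(_design(y, X, ["intercept", "x"]))
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(f.params, beta, atol=1e-10)


def test_ols_singular_names_collinear_columns(rng):
    x = rng.standard_normal(20)
    X = np.column_stack([np.ones(20), x, 2 * x])
    with pytest.raises(ValueError, match="x2"):
        fit_ols(_design(rng.standard_normal(20), X, ["intercept", "x1", "x2"]))


# ---------------------------------------------------------------------------
# SAR


def _sar_setup(seed=0, n=120, rho=0.5):
    rg = np.random.default_rng(seed)
    coords = clustered_coords(rg, n=n, n_clusters=max(10, n // 5))
    X = np.column_stack([np.ones(n), rg.standard_normal(n)])
    y = plant_sar_outcome(coords, X, rho, np.array([1.0, -0.5]), 1.0, rg)
    w = inverse_distance_weights(coords)
    return _design(y, X, ["intercept", "x"], coords), w


def test_sar_fixed_rho_zero_reduces_to_ols():
    d, w = _sar_setup()
    sar = fit_sar(d, w, rho=0.0)
    ols = fit_ols(d)
    np.testing.assert_allclose(sar.params, ols.params, atol=1e-8)


def test_sar_loglik_at_optimum_dominates_rho_zero():
    d, w = _sar_setup(seed=3, rho=0.7)
    free = fit_sar(d, w)
    fixed = fit_sar(d, w, rho=0.0)
    assert free.loglik >= fixed.loglik - 1e-9
    assert free.rho > 0.3


def test_sar_near_zero_rho_data_matches_ols_within_2se():
    """Without a planted lag the ML rho averages near zero and beta agrees
    with OLS within 2 standard errors."""
    rhos, gaps = [], []
    for seed in range(25):
        d, w = _sar_setup(seed=seed, rho=0.0)
        sar = fit_sar(d, w)
        ols = fit_ols(d)
        rhos.append(sar.rho)
        gaps.append(np.abs(sar.params - ols.params) / ols.bse)
        # the covariate effect is stable per replicate; the intercept trades
        # off against rho-hat and is only required to agree on average
        assert gaps[-1][1] <= 2.0
    assert abs(np.mean(rhos)) < 0.05
    assert np.all(np.mean(gaps, axis=0) <= 2.0)


def test_sar_durbin_adds_lagged_covariates():
    d, w = _sar_setup(seed=7)
    f = fit_sar(d, w, lagged_X=True)
    assert f.gamma_names == ["W.x"]
    assert len(f.params) == 3
    assert f.rho_interval[0] < f.rho < f.rho_interval[1]


def test_sar_nonconformable_weights_rejected(rng):
    d, _ = _sar_setup()
    w_bad = inverse_distance_weights(rng.uniform(0, 10, size=(7, 2)))
    with pytest.raises(ValueError, match="conformable"):
        SpatialLag(d, w_bad)


# ---------------------------------------------------------------------------
# GWR


def test_gwr_global_kernel_limit_reproduces_ols(rng):
    n = 80
    coords = rng.uniform(0, 1000, size=(n, 2))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ [1.0, 2.0] + 0.3 * rng.standard_normal(n)
    d = _design(y, X, ["intercept", "x"], coords)
    ols = fit_ols(d)
    g = GWR(d).fit(bandwidth=n, kernel_scale=1e7)
    assert np.abs(g.local_params - ols.params).max() < 1e-4


def test_gwr_recovers_spatially_varying_slope(rng):
    n = 300
    coords = rng.uniform(0, 1000, size=(n, 2))
    x = rng.standard_normal(n)
    beta_u = coords[:, 0] / 1000.0
    y = 1.0 + beta_u * x + 0.2 * rng.standard_normal(n)
    d = _design(y, np.column_stack([np.ones(n), x]), ["intercept", "x"], coords)
    g = fit_gwr(d)
    assert np.corrcoef(beta_u, g.local_params[:, 1])[0, 1] > 0.8


def test_gwr_invariants(rng):
    n = 60
    coords = rng.uniform(0, 500, size=(n, 2))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ [0.5, 1.0] + rng.standard_normal(n)
    g = fit_gwr(_design(y, X, ["intercept", "x"], coords))
    assert np.all(g.coef_min <= g.coef_max)
    assert X.shape[1] < g.trace_S < n
    assert 4 <= g.bandwidth <= n


def test_gwr_requires_coords(rng):
    X = np.column_stack([np.ones(30), rng.standard_normal(30)])
    with pytest.raises(ValueError, match="coordinates"):
        GWR(_design(rng.standard_normal(30), X, ["intercept", "x"]))


# ---------------------------------------------------------------------------
# comparison & standardization


def _fake_fit(aicc, r2=0.5, n=100):
    from revaccess.regression import ModelFit
    return ModelFit(method="m", names=["c"], params=np.zeros(1), bse=np.zeros(1),
                    tvalues=np.zeros(1), pvalues=np.ones(1), std_params=np.zeros(1),
                    r2=r2, adj_r2=r2, aicc=aicc, loglik=0.0, residuals=np.zeros(n),
                    fitted=np.zeros(n), nobs=n, k_params=2)


def test_compare_decisive_at_delta_3():
    out = compare_models({"a": _fake_fit(100.0), "b": _fake_fit(96.0)})
    assert out["best"] == "b" and out["decisive"]
    out = compare_models({"a": _fake_fit(100.0), "b": _fake_fit(98.5)})
    assert out["best"] == "b" and not out["decisive"]


def test_compare_percent_change_arithmetic():
    out = compare_models({"ols": _fake_fit(-400.0, r2=0.5), "gwr": _fake_fit(-500.0, r2=0.6)})
    assert out["vs_ols"]["gwr"]["aicc_pct_change"] == pytest.approx(
        100.0 * (-500.0 - -400.0) / 400.0)
    assert out["vs_ols"]["gwr"]["r2_pct_change"] == pytest.approx(100.0 * 0.1 / 0.5)


def test_compare_rejects_different_sample_sizes():
    with pytest.raises(ValueError, match="not comparable"):
        compare_models({"a": _fake_fit(1.0, n=50), "b": _fake_fit(2.0, n=60)})


def test_standardized_slope_one_when_sds_equal():
    x = np.arange(10.0)
    X = np.column_stack([np.ones(10), x])
    out = standardize_coefficients(np.array([0.0, 1.0]), X, x.copy(), ["intercept", "x"])
    assert out[1] == pytest.approx(1.0)
    assert np.isnan(out[0])


def test_standardized_beta_invariant_to_covariate_scaling(rng):
    n = 40
    x = rng.standard_normal(n)
    y = 2 * x + rng.standard_normal(n)
    f1 = fit_ols(_design(y, np.column_stack([np.ones(n), x]), ["intercept", "x"]))
    f2 = fit_ols(_design(y, np.column_stack([np.ones(n), 10 * x]), ["intercept", "x"]))
    assert f1.std_params[1] == pytest.approx(f2.std_params[1], rel=1e-9)


def test_standardize_hand_computation():
    X = np.column_stack([np.ones(5), [1.0, 2.0, 3.0, 4.0, 5.0]])
    y = np.array([2.0, 4.0, 5.0, 4.0, 6.0])
    f = fit_ols(_design(y, X, ["intercept", "x"]))
    expected = f.params[1] * X[:, 1].std(ddof=1) / y.std(ddof=1)
    assert f.std_params[1] == pytest.approx(expected, rel=1e-12)


def test_aicc_ordering_invariant_to_affine_outcome_rescale(rng):
    """Rescaling y shifts every Gaussian AICc by the same n*ln(a) term, so
    model ordering is preserved."""
    n = 80
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = 1 + x1 + 0.2 * rng.standard_normal(n)
    d_a = _design(y, np.column_stack([np.ones(n), x1]), ["intercept", "x1"])
    d_b = _design(y, np.column_stack([np.ones(n), x2]), ["intercept", "x2"])
    delta = fit_ols(d_a).aicc - fit_ols(d_b).aicc
    y2 = 5.0 * y - 3.0
    d_a2 = _design(y2, d_a.X, d_a.names)
    d_b2 = _design(y2, d_b.X, d_b.names)
    delta2 = fit_ols(d_a2).aicc - fit_ols(d_b2).aicc
    assert delta == pytest.approx(delta2, abs=1e-8)
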