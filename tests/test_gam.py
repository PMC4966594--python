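import json

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import BSpline
from scipy.linalg import helmert

from fermwatch import (
    adjusted_r2,
    build_basis,
    fit_gam,
    fit_glm,
    gcv_score,
    predict,
    residual_diagnostics,
    select_model,
    significance_stars,
    simulate_regression_table,
    term_significance,
)
from fermwatch.gam import CubicSplineBasis, GAMFit

MODEL_VARS = ["T", "DO", "OUR", "CER"]


# --------------------------------------------------------------------------
# basis and penalty


def test_penalty_symmetric_psd_and_blind_to_straight_lines():
    x = np.linspace(0.0, 10.0, 60)
    B, S, basis = build_basis(x, basis_dim=10)
    assert np.array_equal(S, S.T)
    assert np.linalg.eigvalsh(S).min() > -1e-10
    # a straight line lies in the penalty null space
    coef, *_ = np.linalg.lstsq(B, 2.0 + 3.0 * x, rcond=None)
    assert abs(coef @ S @ coef) < 1e-8 * (coef @ coef)


def test_penalty_matches_numerical_integration():
    """The analytic curvature penalty equals numerically integrated products
    of second derivatives (fine Simpson grid on the unit interval)."""
    x = np.linspace(0.0, 1.0, 40)
    basis = CubicSplineBasis.from_data(x, basis_dim=6)
    S = basis.penalty()
    t = np.asarray(basis.knots)
    k = basis.ndim
    grid = np.linspace(0.0, 1.0, 4001)
    D = np.empty((len(grid), k))
    for j in range(k):
        coeffs = np.zeros(k)
        coeffs[j] = 1.0
        D[:, j] = BSpline(t, coeffs, 3, extrapolate=False).derivative(2)(grid)
    from scipy.integrate import simpson

    S_num = np.empty_like(S)
    for i in range(k):
        for j in range(k):
            S_num[i, j] = simpson(D[:, i] * D[:, j], x=grid)
    np.testing.assert_allclose(S, S_num, atol=1e-6)


def test_basis_dim_reduced_with_warning():
    x = np.repeat(np.arange(6.0), 5)
    with pytest.warns(UserWarning, match="basis_dim reduced"):
        _, _, basis = build_basis(x, basis_dim=10)
    assert basis.ndim <= 6
    with pytest.raises(ValueError):
        build_basis(np.array([1.0, 1.0, 2.0, 2.0]), basis_dim=10)


# --------------------------------------------------------------------------
# linear model special case


def test_glm_recovers_exact_linear_law():
    T = np.linspace(0, 30, 20)
    table = {"T": T, "glutamate": 2.0 + 3.0 * T}
    fit = fit_glm(table, ["T"])
    coefs = fit.linear_coefficients
    assert coefs["intercept"] == pytest.approx(2.0, abs=1e-8)
    assert coefs["T"] == pytest.approx(3.0, abs=1e-8)
    assert all(t.edf == pytest.approx(1.0, abs=1e-9) for t in fit.terms)


def test_glm_matches_statsmodels_ols(training_table):
    sm = pytest.importorskip("statsmodels.api")
    fit = fit_glm(training_table, MODEL_VARS)
    X = sm.add_constant(training_table[MODEL_VARS].to_numpy())
    ols = sm.OLS(training_table["glutamate"].to_numpy(), X).fit()
    ours = fit.linear_coefficients
    np.testing.assert_allclose(
        [ours["intercept"], *(ours[v] for v in MODEL_VARS)], ols.params, rtol=1e-8
    )
    np.testing.assert_allclose(fit.fitted, ols.fittedvalues, rtol=1e-8)


def test_infinite_lambda_collapses_to_glm(training_table):
    glm = fit_glm(training_table, MODEL_VARS)
    gam_inf = fit_gam(
        training_table, MODEL_VARS, lambdas={v: np.inf for v in MODEL_VARS}
    )
    np.testing.assert_allclose(gam_inf.fitted, glm.fitted, atol=1e-6)
    np.testing.assert_allclose(
        [t.coefficients[0] for t in gam_inf.terms],
        [t.coefficients[0] for t in glm.terms],
        atol=1e-6,
    )


# --------------------------------------------------------------------------
# penalized fitting


def test_pure_noise_yields_null_model():
    rng = np.random.default_rng(42)
    table = {
        "T": rng.uniform(0, 30, 120),
        "DO": rng.uniform(20, 50, 120),
        "glutamate": 50.0 + rng.normal(0, 2, 120),
    }
    fit = fit_gam(table, ["T", "DO"])
    for term in fit.terms:
        assert term.edf < 1.7
    assert abs(fit.adj_r2) < 0.15


def test_single_smooth_recovers_sine():
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(0, 2 * np.pi, 200))
    table = {"T": x, "glutamate": np.sin(x) + rng.normal(0, 0.1, 200)}
    fit = fit_gam(table, ["T"])
    assert fit.adj_r2 > 0.95
    grid = np.linspace(0.2, 2 * np.pi - 0.2, 50)
    pred = predict(fit, {"T": grid})
    assert np.max(np.abs(pred - np.sin(grid))) < 0.3


def test_smooth_recovery_improves_with_sample_size():
    def ise(n):
        rng = np.random.default_rng(99)
        x = np.sort(rng.uniform(0, 10, n))
        y = np.log1p(x) * 5 + rng.normal(0, 0.5, n)
        fit = fit_gam({"T": x, "glutamate": y}, ["T"])
        grid = np.linspace(0.5, 9.5, 100)
        return float(np.mean((predict(fit, {"T": grid}) - 5 * np.log1p(grid)) ** 2))

    assert ise(600) < ise(60)


def test_predict_reproduces_fitted_and_centring(gam_fit, training_table):
    pred = predict(gam_fit, training_table)
    np.testing.assert_allclose(pred, gam_fit.fitted, atol=1e-10)
    measured = training_table["glutamate"].to_numpy()
    np.testing.assert_allclose(measured - pred, gam_fit.residuals, atol=1e-10)
    # sum-to-zero centring makes the intercept the mean response
    assert np.mean(gam_fit.fitted) == pytest.approx(gam_fit.intercept, abs=1e-8)
    assert abs(gam_fit.residuals.mean()) < 1e-8 * measured.std()


def test_predict_matches_manual_basis_evaluation(gam_fit):
    """Hand evaluation through scipy B-splines, centring and the constraint
    transform reproduces predict to 1e-10."""
    row = {"T": 11.0, "DO": 30.0, "OUR": 80.0, "CER": 90.0}
    total = gam_fit.intercept
    for term in gam_fit.terms:
        basis = term.basis
        u = (row[term.variable] - basis.lo) / (basis.hi - basis.lo)
        t = np.asarray(basis.knots)
        Brow = np.array(
            [
                BSpline(t, np.eye(basis.ndim)[k], 3, extrapolate=False)(u)
                for k in range(basis.ndim)
            ]
        )
        Z = helmert(basis.ndim).T
        total += float((Brow - term.col_means) @ Z @ term.coefficients)
    pred = predict(gam_fit, {k: np.array([v]) for k, v in row.items()})
    assert pred[0] == pytest.approx(total, abs=1e-10)


def test_predict_requires_all_variables(gam_fit):
    with pytest.raises(ValueError, match="CER"):
        predict(gam_fit, {"T": np.array([1.0]), "DO": np.array([30.0]), "OUR": np.array([60.0])})


def test_extrapolation_is_linear(gam_fit):
    lo = 40.0  # below any training CER
    grid = np.array([lo - 30, lo - 20, lo - 10])
    term = next(t for t in gam_fit.terms if t.variable == "CER")
    vals = term.evaluate(grid)
    second_diff = vals[2] - 2 * vals[1] + vals[0]
    assert abs(second_diff) < 1e-8


def test_affine_rescaling_invariance(training_table):
    fit = fit_gam(training_table, MODEL_VARS)
    scaled = training_table.copy()
    scaled["CER"] = scaled["CER"] / 1000.0 + 7.0  # different units + offset
    fit2 = fit_gam(scaled, MODEL_VARS)
    np.testing.assert_allclose(fit2.fitted, fit.fitted, atol=1e-6)


def test_edf_additivity_and_bounds(gam_fit):
    assert gam_fit.total_edf == pytest.approx(
        1.0 + sum(t.edf for t in gam_fit.terms), abs=1e-8
    )
    for term in gam_fit.terms:
        assert 1.0 - 1e-6 <= term.edf <= term.basis.ndim


def test_zero_variance_covariate_rejected(training_table):
    table = training_table.copy()
    table["flat"] = 5.0
    with pytest.raises(ValueError, match="flat"):
        fit_gam(table, ["T", "flat"])


# --------------------------------------------------------------------------
# summary statistics


def test_gcv_and_adj_r2_formulas_on_toy_table():
    T = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.0, 2.9, 5.2, 6.8, 9.1, 11.0])
    fit = fit_glm({"T": T, "glutamate": y}, ["T"])
    # hand computation: OLS slope/intercept, RSS, edf = 2
    slope = np.cov(T, y, bias=True)[0, 1] / np.var(T)
    intercept = y.mean() - slope * T.mean()
    rss = float(np.sum((y - intercept - slope * T) ** 2))
    n, edf = 6, 2.0
    assert gcv_score(fit) == pytest.approx(n * rss / (n - edf) ** 2, rel=1e-9)
    tss = float(np.sum((y - y.mean()) ** 2))
    assert adjusted_r2(fit) == pytest.approx(
        1 - (rss / (n - edf)) / (tss / (n - 1)), rel=1e-9
    )


def test_perfect_fit_has_unit_adj_r2():
    T = np.linspace(0, 5, 8)
    fit = fit_glm({"T": T, "glutamate": 4.0 + 0.5 * T}, ["T"])
    assert adjusted_r2(fit) == pytest.approx(1.0, abs=1e-9)


def test_significance_stars_convention():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""


# --------------------------------------------------------------------------
# term significance


def test_strong_term_is_highly_significant():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 30, 100)
    z = rng.uniform(0, 1, 100)
    table = {"T": x, "pH": z, "glutamate": 2 * x + rng.normal(0, 0.5, 100)}
    pvals = term_significance(fit_gam(table, ["T", "pH"]))
    assert pvals["T"] < 1e-3
    assert pvals["pH"] > 0.05


def test_null_term_pvalues_roughly_uniform():
    """A covariate unrelated to the response is rejected at ~the nominal
    rate over replicates."""
    ps = []
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        x = rng.uniform(0, 30, 80)
        z = rng.uniform(0, 100, 80)
        table = {"T": x, "SS": z, "glutamate": 0.5 * x + rng.normal(0, 1, 80)}
        ps.append(term_significance(fit_gam(table, ["T", "SS"]))["SS"])
    ps = np.array(ps)
    assert (ps < 0.05).mean() <= 0.12
    assert 0.3 < ps.mean() < 0.75


def test_all_zero_term_reports_p_one(gam_fit, training_table):
    import copy

    fit = copy.deepcopy(gam_fit)
    fit.terms[1].coefficients[:] = 0.0
    pvals = term_significance(fit, table=training_table)
    assert pvals[fit.terms[1].variable] == 1.0


# --------------------------------------------------------------------------
# model selection


def test_single_informative_candidate_retained():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 30, 80)
    table = {"T": x, "glutamate": 3 * x + rng.normal(0, 1, 80)}
    fit = select_model(table, ["T"])
    assert fit.variables == ["T"]


def test_all_noise_candidates_rejected():
    rng = np.random.default_rng(6)
    table = {
        "SS": rng.uniform(400, 900, 80),
        "pH": rng.uniform(6.9, 7.3, 80),
        "glutamate": rng.normal(50, 2, 80),
    }
    with pytest.raises(ValueError, match="informative"):
        select_model(table, ["SS", "pH"])


def test_backward_elimination_matches_best_subset_gcv():
    """On a clearly-structured table, backward elimination lands on the
    same variable set as exhaustive GCV-optimal subset search."""
    from itertools import combinations

    table = simulate_regression_table(100, seed=8, null_extra=True)
    candidates = ["T", "OUR", "SS", "pH"]
    best, best_gcv = None, np.inf
    for r in range(1, 5):
        for subset in combinations(candidates, r):
            gcv = fit_gam(table, list(subset)).gcv
            if gcv < best_gcv:
                best, best_gcv = set(subset), gcv
    selected = set(select_model(table, candidates).variables)
    assert selected == best == {"T", "OUR"}


# --------------------------------------------------------------------------
# diagnostics and serialization


def test_qq_pairs_on_identity_for_exact_normal_residuals():
    n = 200
    pp = (np.arange(1, n + 1) - 0.5) / n
    from scipy.stats import norm

    residuals = norm.ppf(pp)
    fit = GAMFit(
        variables=[],
        intercept=0.0,
        terms=[],
        residuals=residuals,
        fitted=np.zeros(n),
        n=n,
        total_edf=1.0,
        sigma2=1.0,
        gcv=1.0,
        adj_r2=0.0,
        cov_unscaled=np.eye(1),
    )
    d = residual_diagnostics(fit)
    np.testing.assert_allclose(d.qq_theoretical, d.qq_sample, atol=1e-9)
    assert d.rmse == pytest.approx(np.sqrt(np.mean(residuals**2)), rel=1e-12)


def test_diagnostics_on_holdout(gam_fit, train_test):
    from fermwatch import align_offline_online

    _, test = train_test
    table = align_offline_online([test])
    d = residual_diagnostics(gam_fit, table)
    np.testing.assert_allclose(
        d.residuals, table["glutamate"].to_numpy() - predict(gam_fit, table)
    )
    assert d.pearson_r > 0.98
    assert d.rmse < 6.0
    assert d.hist_counts.sum() == len(table)


def test_serialization_roundtrip(gam_fit, training_table, tmp_path):
    path = tmp_path / "model.json"
    gam_fit.to_json(str(path))
    back = GAMFit.from_json(str(path))
    np.testing.assert_array_equal(predict(back, training_table), predict(gam_fit, training_table))
    assert back.gcv == gam_fit.gcv
    assert back.total_edf == gam_fit.total_edf
    # significance reproducible after reload when the table is supplied
    a = term_significance(gam_fit)
    b = term_significance(back, table=training_table)
    for v in gam_fit.variables:
        assert b[v] == pytest.approx(a[v], rel=1e-6)
    json.loads(path.read_text())  # valid JSON document
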