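"""Estimator layer: closed-form oracles, statsmodels cross-checks, design."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyiv.estimators import (
    ModelSpec,
    build_design,
    fit_2sls,
    fit_model,
    fit_ols,
)


def _toy_regression(n=7, seed=9):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"intercept": np.ones(n), "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
    )
    y = 1.0 + 2.0 * X["x1"].to_numpy() - 0.5 * X["x2"].to_numpy() + rng.normal(
        scale=0.3, size=n
    )
    return y, X


# --- OLS --------------------------------------------------------------------


def test_ols_matches_normal_equations_oracle():
    y, X = _toy_regression()
    fit = fit_ols(y, X)
    Xv = X.to_numpy()
    beta = np.linalg.solve(Xv.T @ Xv, Xv.T @ y)
    np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=0, atol=1e-10)
    resid = y - Xv @ beta
    sigma2 = resid @ resid / (len(y) - Xv.shape[1])
    cov = sigma2 * np.linalg.inv(Xv.T @ Xv)
    np.testing.assert_allclose(fit.bse.to_numpy(), np.sqrt(np.diag(cov)), rtol=1e-10)
    tss = ((y - y.mean()) ** 2).sum()
    assert fit.r2 == pytest.approx(1 - (resid @ resid) / tss, abs=1e-12)


def test_ols_pvalues_use_t_distribution():
    y, X = _toy_regression()
    fit = fit_ols(y, X)
    expect = 2 * stats.t.sf(np.abs(fit.tvalues.to_numpy()), fit.df_resid)
    np.testing.assert_allclose(fit.pvalues.to_numpy(), expect, rtol=1e-12)


def test_ols_residual_orthogonality_invariant(default_sample):
    _, pheno, _ = default_sample
    y, X = build_design(pheno.table, ModelSpec(preset="full"), include_focal=True)
    fit = fit_ols(y, X)
    assert np.abs(X.to_numpy().T @ fit.resid).max() / fit.n < 1e-8
    assert 0.0 <= fit.r2 <= 1.0


def test_ols_matches_statsmodels(default_sample):
    sm = pytest.importorskip("statsmodels.api")
    _, pheno, _ = default_sample
    y, X = build_design(pheno.table, ModelSpec(preset="full"), include_focal=True)
    ours = fit_ols(y, X)
    theirs = sm.OLS(y, X.to_numpy()).fit()
    np.testing.assert_allclose(ours.params.to_numpy(), theirs.params, atol=1e-9)
    np.testing.assert_allclose(ours.bse.to_numpy(), theirs.bse, rtol=1e-9)
    assert ours.r2 == pytest.approx(theirs.rsquared, abs=1e-10)


def test_ols_rejects_rank_deficiency_naming_columns():
    y, X = _toy_regression()
    X["x1_copy"] = X["x1"]
    with pytest.raises(ValueError, match="x1"):
        fit_ols(y, X)


def test_ols_rejects_more_columns_than_rows():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
    with pytest.raises(ValueError, match="columns"):
        fit_ols(rng.normal(size=3), X)


# --- 2SLS -------------------------------------------------------------------


def test_wald_ratio_oracle():
    """Just-identified IV with only an intercept equals the Wald ratio."""
    rng = np.random.default_rng(3)
    n = 8
    z = rng.normal(size=n)
    x = 1.5 * z + rng.normal(size=n)
    y = 0.7 * x + rng.normal(size=n)
    fit = fit_2sls(
        y, x,
        pd.DataFrame({"z": z}),
        pd.DataFrame({"intercept": np.ones(n)}),
        focal_name="x",
    )
    zc, xc, yc = z - z.mean(), x - x.mean(), y - y.mean()
    wald = (zc @ yc) / (zc @ xc)
    assert fit.second_stage.coef("x") == pytest.approx(wald, abs=1e-10)
    assert not fit.sargan_result.applicable


def test_first_stage_f_equals_t_squared_single_instrument(default_sample):
    _, pheno, _ = default_sample
    fit = fit_model(pheno.table, ModelSpec(preset="full"), method="2sls")
    t = float(fit.first_stage.tvalues["pgs_height"])
    assert fit.f_excluded == pytest.approx(t**2, rel=1e-8)
    assert fit.f_pvalue == pytest.approx(
        stats.f.sf(fit.f_excluded, 1, fit.first_stage.df_resid), rel=1e-10
    )


def test_2sls_matches_statsmodels(default_sample):
    gmm = pytest.importorskip("statsmodels.sandbox.regression.gmm")
    _, pheno, _ = default_sample
    df = pheno.table
    y, X = build_design(df, ModelSpec(preset="full"), include_focal=False)
    Z = pd.DataFrame({"pgs_height": df["pgs_height"].to_numpy()}, index=df.index)
    ours = fit_2sls(y, df["height"].to_numpy(float), Z, X)
    exog = np.column_stack([df["height"].to_numpy(float), X.to_numpy()])
    instr = np.column_stack([Z.to_numpy(), X.to_numpy()])
    theirs = gmm.IV2SLS(y, exog, instrument=instr).fit()
    np.testing.assert_allclose(
        ours.second_stage.params.to_numpy(), theirs.params, atol=1e-8
    )
    np.testing.assert_allclose(ours.second_stage.bse.to_numpy(), theirs.bse, rtol=1e-8)


def test_2sls_standard_errors_use_structural_residual():
    """The reported RSS comes from the observed-regressor residual, which
    exceeds the stage-two plug-in RSS."""
    rng = np.random.default_rng(8)
    n = 200
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    fit = fit_2sls(
        y, x, pd.DataFrame({"z": z}), pd.DataFrame({"intercept": np.ones(n)}),
        focal_name="x",
    )
    beta = fit.second_stage.params.to_numpy()
    struct = y - beta[0] * x - beta[1]
    assert fit.second_stage.rss == pytest.approx(float(struct @ struct), rel=1e-12)
    np.testing.assert_allclose(fit.second_stage.resid, struct, atol=1e-10)


def test_null_instrument_f_distribution_calibrated():
    """With an irrelevant instrument the excluded-F follows F(1, n-2)."""
    rng = np.random.default_rng(77)
    n, reps = 80, 600
    fs, ps = [], []
    for _ in range(reps):
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fit = fit_2sls(
            y, x, pd.DataFrame({"z": z}), pd.DataFrame({"intercept": np.ones(n)}),
            focal_name="x",
        )
        fs.append(fit.f_excluded)
        ps.append(fit.f_pvalue)
    m = n - 2
    assert np.mean(fs) == pytest.approx(m / (m - 2), abs=0.25)
    assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.09


def test_sargan_matches_auxiliary_regression_oracle():
    rng = np.random.default_rng(15)
    n = 40
    z1, z2 = rng.normal(size=n), rng.normal(size=n)
    x = z1 + 0.5 * z2 + rng.normal(size=n)
    y = 0.3 * x + rng.normal(size=n)
    X = pd.DataFrame({"intercept": np.ones(n)})
    Z = pd.DataFrame({"z1": z1, "z2": z2})
    fit = fit_2sls(y, x, Z, X, focal_name="x")
    sg = fit.sargan_result
    assert sg.applicable and sg.df == 1
    # brute-force n * R^2 of structural residuals on [Z, X]
    u = fit.second_stage.resid
    W = np.column_stack([z1, z2, np.ones(n)])
    coef, *_ = np.linalg.lstsq(W, u, rcond=None)
    uhat = W @ coef
    r2 = 1 - ((u - uhat) ** 2).sum() / ((u - u.mean()) ** 2).sum()
    assert sg.statistic == pytest.approx(n * r2, abs=1e-10)
    assert sg.pvalue == pytest.approx(stats.chi2.sf(n * r2, 1), rel=1e-10)


def test_sargan_not_applicable_when_just_identified(default_sample):
    _, pheno, _ = default_sample
    fit = fit_model(pheno.table, ModelSpec(preset="full"), method="2sls")
    assert not fit.sargan_result.applicable
    assert fit.sargan_result.statistic is None


def test_quadratic_instrument_enters_first_stage(default_sample):
    _, pheno, _ = default_sample
    fit = fit_model(
        pheno.table, ModelSpec(preset="full"), method="2sls",
        quadratic_instrument=True,
    )
    assert "pgs_height_sq" in fit.first_stage.params.index
    assert fit.n_instruments == 2
    assert fit.sargan_result.applicable and fit.sargan_result.df == 1


def test_2sls_requires_an_instrument():
    rng = np.random.default_rng(1)
    n = 10
    with pytest.raises(ValueError, match="instrument"):
        fit_2sls(
            rng.normal(size=n), rng.normal(size=n),
            pd.DataFrame(index=range(n)),
            pd.DataFrame({"intercept": np.ones(n)}),
        )


# --- design construction ----------------------------------------------------


def test_build_design_minimal_columns(default_sample):
    _, pheno, _ = default_sample
    _, X = build_design(pheno.table, ModelSpec(preset="minimal"))
    assert list(X.columns) == ["intercept", "male", "age", "age_sq"]


def test_build_design_full_column_count(default_sample):
    _, pheno, _ = default_sample
    df = pheno.table
    n_prov = df["province"].nunique()
    _, X = build_design(df, ModelSpec(preset="full"))
    expected = 4 + 1 + (n_prov - 1) + 41 + 7
    assert X.shape[1] == expected
    _, Xf = build_design(df, ModelSpec(preset="full"), include_focal=True)
    assert Xf.shape[1] == expected + 1 and "height" in Xf.columns
    # benchmark drops the preference and auxiliary-PGS block
    _, Xb = build_design(df, ModelSpec(preset="benchmark"))
    assert Xb.shape[1] == expected - 7


def test_build_design_drops_largest_ancestry_and_modal_province(default_sample):
    _, pheno, _ = default_sample
    df = pheno.table
    _, X = build_design(df, ModelSpec(preset="full"))
    anc_cols = [c for c in df.columns if c.startswith("anc_")]
    largest = df[anc_cols].mean().idxmax()
    assert largest == "anc_northern_han" and largest not in X.columns
    modal = df["province"].value_counts().idxmax()
    assert f"province_{modal}" not in X.columns


def test_build_design_single_sex_subsample_drops_constant(default_sample):
    _, pheno, _ = default_sample
    _, X = build_design(pheno.table, ModelSpec(preset="full", subsample="male"))
    assert "male" not in X.columns
    assert X.shape[0] == int(pheno.table["male"].sum())


def test_model_spec_validation():
    with pytest.raises(ValueError, match="preset"):
        ModelSpec(preset="huge")
    with pytest.raises(ValueError, match="subsample"):
        ModelSpec(subsample="elderly")
    with pytest.raises(ValueError, match="instrument"):
        ModelSpec(focal="height", instruments=("height",))


def test_fit_model_rejects_unknown_method(default_sample):
    _, pheno, _ = default_sample
    with pytest.raises(ValueError, match="method"):
        fit_model(pheno.table, ModelSpec(), method="gmm")


def test_fit_model_2sls_needs_score_column(default_sample):
    _, pheno, _ = default_sample
    df = pheno.table.drop(columns=["pgs_height"])
    with pytest.raises(KeyError):
        fit_model(df, ModelSpec(preset="full"), method="2sls")
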