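"""Validity battery: balance oracle, reduced form, attenuation, overid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import make_pheno_frame
from polyiv.estimators import ModelSpec, fit_model
from polyiv.replication import run_monte_carlo
from polyiv.scoring import ScoreVector
from polyiv.validity import (
    BALANCE_VARIABLES,
    balance_table,
    compare_ols_iv,
    overid_quadratic,
    reduced_form,
    run_validity,
    trait_panels,
)


def _scores_for(df, seed=0):
    rng = np.random.default_rng(seed)
    return ScoreVector(
        sample_ids=df["sample_id"].to_numpy(),
        score=rng.normal(size=len(df)),
        n_imputed=np.zeros(len(df), dtype=int),
        summary={},
    )


def test_balance_table_welch_oracle():
    df = make_pheno_frame(60, seed=3)
    scores = _scores_for(df, seed=4)
    bal = balance_table(df, scores)
    assert list(bal["variable"]) == list(BALANCE_VARIABLES)
    hi = scores.score > scores.score.mean()
    row = bal.loc[bal["variable"] == "height"].iloc[0]
    a = df.loc[hi, "height"].to_numpy()
    b = df.loc[~hi, "height"].to_numpy()
    # hand-computed Welch t and Welch-Satterthwaite df
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    assert row["t"] == pytest.approx(t, abs=1e-10)
    assert row["p"] == pytest.approx(2 * stats.t.sf(abs(t), dof), abs=1e-10)
    assert row["difference"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)
    assert bal.attrs["n_higher"] + bal.attrs["n_lower"] == len(df)
    assert bal.attrs["n_higher"] == int(hi.sum())


def test_balance_table_flags_degenerate_variable():
    df = make_pheno_frame(30, seed=5)
    df["trust"] = 5.0  # identical in both groups
    bal = balance_table(df, _scores_for(df, seed=6))
    row = bal.loc[bal["variable"] == "trust"].iloc[0]
    assert bool(row["degenerate"])
    assert np.isnan(row["t"]) and row["p"] == 1.0


def test_balance_table_handles_one_person_group():
    df = make_pheno_frame(10)
    sv = _scores_for(df)
    sv.score[:] = np.linspace(0, 1, 10)
    sv.score[0] = 1e6  # outlier pulls the mean above every other point
    bal = balance_table(df, sv)  # still two non-empty groups
    assert bal.attrs["n_higher"] == 1
    assert bal.attrs["n_lower"] == 9


def test_reduced_form_has_three_nested_specs(default_sample):
    _, pheno, scores = default_sample
    fits = reduced_form(pheno.table, scores)
    assert len(fits) == 3
    assert [f.n for f in fits] == [pheno.n] * 3
    # each spec nests the previous one
    assert len(fits[0].colnames) < len(fits[1].colnames) < len(fits[2].colnames)
    for f in fits:
        assert "pgs_height" in f.params.index
        assert "height" not in f.params.index


def test_reduced_form_slope_consistent_with_planted_path(default_sample):
    """The score -> earnings reduced form equals the first-stage slope times
    the causal height effect, up to sampling noise."""
    cohort, pheno, scores = default_sample
    cfg = cohort.truth.config
    fit = reduced_form(pheno.table, scores)[0]
    implied = cfg.alpha1_pgs * cfg.beta_height_true
    se = float(fit.bse["pgs_height"])
    assert abs(fit.coef("pgs_height") - implied) < 4 * se


def test_compare_ols_iv_verdict(default_sample):
    _, pheno, _ = default_sample
    ols = fit_model(pheno.table, ModelSpec(preset="full"), method="ols")
    iv = fit_model(pheno.table, ModelSpec(preset="full"), method="2sls")
    verdict = compare_ols_iv(ols, iv)
    assert verdict.beta_ols == pytest.approx(ols.coef("height"))
    assert verdict.beta_iv == pytest.approx(iv.second_stage.coef("height"))
    assert verdict.difference == pytest.approx(verdict.beta_iv - verdict.beta_ols)
    assert verdict.attenuated == (verdict.beta_iv < verdict.beta_ols)


def test_compare_ols_iv_rejects_mismatched_samples(default_sample):
    _, pheno, _ = default_sample
    ols = fit_model(pheno.table, ModelSpec(preset="full"), method="ols")
    iv = fit_model(
        pheno.table, ModelSpec(preset="full", subsample="male"), method="2sls"
    )
    with pytest.raises(ValueError, match="different samples"):
        compare_ols_iv(ols, iv)


def test_overid_quadratic_reports_sargan(default_sample):
    _, pheno, scores = default_sample
    fit = overid_quadratic(pheno.table, scores)
    assert fit.n_instruments == 2
    assert fit.sargan_result.applicable and fit.sargan_result.df == 1
    assert fit.sargan_result.statistic >= 0.0


def test_trait_panels_match_cov_var_oracle(default_sample):
    _, pheno, scores = default_sample
    pa, pb = trait_panels(pheno.table, scores)
    assert list(pa["variable"]) == ["schooling", "risk_loving", "altruism", "trust"]
    assert list(pb["variable"]) == [
        "pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction"
    ]
    h = pheno.table["height"].to_numpy()
    yv = pheno.table["schooling"].to_numpy()
    hc = h - h.mean()
    slope = (hc @ (yv - yv.mean())) / (hc @ hc)
    assert pa.loc[0, "height_coef"] == pytest.approx(slope, abs=1e-10)


def test_run_validity_flags_consistent(default_sample):
    _, pheno, scores = default_sample
    report = run_validity(pheno.table, scores)
    assert set(report.flags) == {
        "relevance_f_above_10",
        "balance_non_height_rejections_5pct",
        "reduced_form_pgs_significant",
        "iv_attenuated",
        "sargan_reject_5pct",
    }
    assert report.flags["relevance_f_above_10"] is True
    assert report.flags["iv_attenuated"] == report.attenuation.attenuated
    assert len(report.reduced_form) == 3
    assert report.overidentified.sargan_result.applicable


def test_balance_type1_error_calibrated(null_battery_500):
    """Module invariant: with the default clean-instrument DGP the ten
    non-height balance rows reject at 5% with frequency in [2%, 8%]."""
    rate = (
        null_battery_500["balance_rejections"].sum()
        / null_battery_500["balance_rows"].sum()
    )
    assert 0.02 <= rate <= 0.08


# --- directional properties of the confounding design -----------------------


def test_attenuation_rate_monotone_in_confounding(mc200, make_scaled_config):
    """Positive confounding puts the IV estimate below OLS more often than
    not; with the confounder's income path switched off the ordering is a
    coin flip; a negative income path reverses it."""
    per_rep, _ = mc200
    assert per_rep["iv_lt_ols"].mean() > 0.60

    def rate(cfg, seed, reps=60):
        per, _ = run_monte_carlo(cfg, reps, seed=seed)
        return per["iv_lt_ols"].mean()

    zero = rate(make_scaled_config(theta_income=0.0, kappa_risk=0.0), seed=101)
    neg = rate(make_scaled_config(theta_income=-0.5, kappa_risk=0.0), seed=102)
    assert 0.35 <= zero <= 0.65
    assert neg < 0.45


def test_linear_pleiotropy_shifts_iv_by_planted_ratio(make_scaled_config):
    """A direct score -> earnings effect p moves the IV estimand to
    beta + p / alpha1: both instruments inherit the same contaminated
    Wald ratio, which is why the Sargan test cannot see it."""
    cfg = make_scaled_config(pleiotropy_effect=0.15)
    per, summary = run_monte_carlo(cfg, 60, seed=103)
    target = cfg.beta_height_true + cfg.pleiotropy_effect / cfg.alpha1_pgs
    assert summary.loc["iv_full", "truth"] == pytest.approx(target, abs=1e-12)
    mean_iv = per["iv_full"].mean()
    mc_se = per["iv_full"].std(ddof=1) / np.sqrt(len(per))
    assert abs(mean_iv - target) < 4 * mc_se
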