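"""Instrument-validity battery for the polygenic height score.

Three criteria back a Mendelian-randomization instrument:

* relevance — the score predicts height; delegated to the excluded-
  instrument first-stage F of :mod:`polyiv.estimators`;
* independence — individuals above and below the mean score should
  differ only in height; checked by an unadjusted Welch-t balance table;
* exclusion — the score should move earnings only through height;
  probed three ways: the reduced form of log earnings on the score with
  height excluded, the attenuation comparison (IV estimate below the
  OLS estimate under positive confounding), and a quadratic-score
  overidentification (Sargan) test.

Trait panels quantify how height co-moves with the preference scores and
the auxiliary polygenic scores, with and without adjustment for the
height score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    IVFit,
    ModelSpec,
    RegressionFit,
    build_design,
    fit_2sls,
    fit_ols,
)
from .io_formats import PhenotypeTable
from .scoring import ScoreVector, split_by_mean

#: Table-2-style default comparison variables.
BALANCE_VARIABLES = (
    "log_earnings", "height", "age", "schooling",
    "risk_loving", "altruism", "trust",
    "pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction",
)


@dataclass
class AttenuationVerdict:
    beta_ols: float
    beta_iv: float
    difference: float
    attenuated: bool   # True iff beta_iv < beta_ols


@dataclass
class ValidityReport:
    balance: pd.DataFrame
    reduced_form: list[RegressionFit]
    attenuation: AttenuationVerdict
    overidentified: IVFit
    flags: dict


def _as_df(pheno: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
    return pheno.table if isinstance(pheno, PhenotypeTable) else pheno


def balance_table(
    pheno: PhenotypeTable | pd.DataFrame,
    scores: ScoreVector,
    variables: tuple[str, ...] = BALANCE_VARIABLES,
) -> pd.DataFrame:
    """Unadjusted two-group comparison by the above/below-mean score split.

    One row per variable: group means with standard errors, the
    higher-minus-lower difference, Welch's t and its p-value.  Rows where
    either group has zero variance are flagged and left without a t.
    """
    df = _as_df(pheno)
    labels = split_by_mean(scores).to_numpy()
    hi, lo = labels == "higher", labels == "lower"
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("empty score group")
    rows = []
    for var in variables:
        a = df.loc[hi, var].to_numpy(dtype=float)
        b = df.loc[lo, var].to_numpy(dtype=float)
        degenerate = (
            len(a) < 2 or len(b) < 2
            or a.var(ddof=1) == 0 or b.var(ddof=1) == 0
        )
        if degenerate and np.array_equal(np.unique(a), np.unique(b)):
            t, p = np.nan, 1.0
        elif degenerate:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": var,
                "mean_higher": a.mean(),
                "se_higher": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan,
                "mean_lower": b.mean(),
                "se_lower": b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else np.nan,
                "difference": a.mean() - b.mean(),
                "t": t,
                "p": p,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_higher"] = int(hi.sum())
    out.attrs["n_lower"] = int(lo.sum())
    return out


def reduced_form(
    pheno: PhenotypeTable | pd.DataFrame, scores: ScoreVector
) -> list[RegressionFit]:
    """Log earnings on the height score with observed height excluded.

    Three nested specifications: (1) score plus preference and
    auxiliary-PGS controls; (2) adding gender, age, age squared and
    schooling; (3) adding province fixed effects and ancestry.
    """
    df = _as_df(pheno).copy()
    df["pgs_height"] = scores.score
    prefs = ["risk_loving", "altruism", "trust",
             "pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction"]
    y = df["log_earnings"].to_numpy(dtype=float)

    fits = []
    X1 = pd.DataFrame({"intercept": np.ones(len(df))})
    X1["pgs_height"] = df["pgs_height"].to_numpy()
    for c in prefs:
        X1[c] = df[c].to_numpy(dtype=float)
    fits.append(fit_ols(y, X1))

    X2 = X1.copy()
    X2["male"] = df["male"].to_numpy(dtype=float)
    X2["age"] = df["age"].to_numpy(dtype=float)
    X2["age_sq"] = X2["age"] ** 2
    X2["schooling"] = df["schooling"].to_numpy(dtype=float)
    fits.append(fit_ols(y, X2))

    # spec 3 reuses the full design builder, swapping height for the score
    spec = ModelSpec(preset="full")
    _, X3 = build_design(df, spec, include_focal=False)
    X3 = X3.copy()
    X3["pgs_height"] = df["pgs_height"].to_numpy()
    fits.append(fit_ols(y, X3))
    return fits


def compare_ols_iv(ols: RegressionFit, iv: IVFit, focal: str = "height") -> AttenuationVerdict:
    """Attenuation check: under positive confounding the IV estimate
    should fall below the OLS estimate."""
    if ols.n != iv.n:
        raise ValueError(
            f"OLS (n={ols.n}) and IV (n={iv.n}) fit on different samples"
        )
    b_ols = ols.coef(focal)
    b_iv = iv.second_stage.coef(focal)
    return AttenuationVerdict(
        beta_ols=b_ols,
        beta_iv=b_iv,
        difference=b_iv - b_ols,
        attenuated=b_iv < b_ols,
    )


def overid_quadratic(
    pheno: PhenotypeTable | pd.DataFrame,
    scores: ScoreVector,
    spec: ModelSpec | None = None,
) -> IVFit:
    """2SLS with [score, centred score squared] as instruments.

    Centring before squaring decorrelates the quadratic term from the
    linear one (numerical conditioning; the fitted space is unchanged).
    The Sargan statistic is available on the returned fit.
    """
    spec = spec or ModelSpec(preset="full")
    df = _as_df(pheno).copy()
    df["pgs_height"] = scores.score
    y, X = build_design(df, spec, include_focal=False)
    s = df["pgs_height"].to_numpy()
    Z = pd.DataFrame(
        {"pgs_height": s, "pgs_height_sq": (s - s.mean()) ** 2}, index=df.index
    )
    focal = df[spec.focal].to_numpy(dtype=float)
    return fit_2sls(y, focal, Z, X, focal_name=spec.focal)


def trait_panels(
    pheno: PhenotypeTable | pd.DataFrame, scores: ScoreVector
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Height-trait co-movement tables.

    Panel A regresses schooling and the three preference scores on
    height, then on height plus the height score; panel B does the same
    for the four auxiliary polygenic scores.
    """
    df = _as_df(pheno)
    height = df["height"].to_numpy(dtype=float)
    s = scores.score

    def panel(columns: tuple[str, ...]) -> pd.DataFrame:
        rows = []
        for var in columns:
            yv = df[var].to_numpy(dtype=float)
            X1 = pd.DataFrame({"intercept": np.ones(len(df)), "height": height})
            f1 = fit_ols(yv, X1)
            X2 = X1.copy()
            X2["pgs_height"] = s
            f2 = fit_ols(yv, X2)
            rows.append(
                {
                    "variable": var,
                    "height_coef": f1.coef("height"),
                    "height_se": float(f1.bse["height"]),
                    "height_p": float(f1.pvalues["height"]),
                    "height_coef_adj": f2.coef("height"),
                    "height_se_adj": float(f2.bse["height"]),
                    "pgs_coef": f2.coef("pgs_height"),
                    "pgs_se": float(f2.bse["pgs_height"]),
                }
            )
        return pd.DataFrame(rows)

    panel_a = panel(("schooling", "risk_loving", "altruism", "trust"))
    panel_b = panel(
        ("pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction")
    )
    return panel_a, panel_b


def run_validity(
    pheno: PhenotypeTable | pd.DataFrame, scores: ScoreVector
) -> ValidityReport:
    """Assemble the full validity battery on one analytical sample."""
    df = _as_df(pheno).copy()
    df["pgs_height"] = scores.score
    spec = ModelSpec(preset="full")

    bal = balance_table(df, scores)
    rf = reduced_form(df, scores)
    y, X = build_design(df, spec, include_focal=True)
    ols = fit_ols(y, X)
    y2, X2 = build_design(df, spec, include_focal=False)
    iv = fit_2sls(
        y2,
        df["height"].to_numpy(dtype=float),
        pd.DataFrame({"pgs_height": df["pgs_height"].to_numpy()}, index=df.index),
        X2,
    )
    verdict = compare_ols_iv(ols, iv)
    over = overid_quadratic(df, scores, spec)

    non_height = bal.loc[bal["variable"] != "height"]
    flags = {
        "relevance_f_above_10": iv.f_excluded >= 10.0,
        "balance_non_height_rejections_5pct": int((non_height["p"] < 0.05).sum()),
        "reduced_form_pgs_significant": any(
            f.pvalues["pgs_height"] < 0.05 for f in rf
        ),
        "iv_attenuated": verdict.attenuated,
        "sargan_reject_5pct": bool(
            over.sargan_result.applicable and over.sargan_result.pvalue < 0.05
        ),
    }
    return ValidityReport(
        balance=bal,
        reduced_form=rf,
        attenuation=verdict,
        overidentified=over,
        flags=flags,
    )
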