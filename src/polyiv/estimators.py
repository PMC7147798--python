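"""OLS and two-stage least squares with the diagnostics the analysis reports.

The wage equation log(Y) = b0 + b1*Height + X*b2 + u is fit by OLS under
three nested covariate presets, and by 2SLS with the height polygenic
score (optionally plus its centred square) instrumenting observed
height.  Estimation is from first principles on a QR decomposition:
coefficients, classical standard errors, the excluded-instrument
first-stage F from a nested residual-sum-of-squares comparison, and the
Sargan overidentification statistic (n * R-squared of the structural
residuals on instruments and exogenous regressors).

Second-stage 2SLS standard errors use the structural residual
y - b1*Height_observed - X*g, not the stage-two plug-in residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_formats import PhenotypeTable

PRESET_MINIMAL = "minimal"
PRESET_BENCHMARK = "benchmark"
PRESET_FULL = "full"

_PREFERENCE_COLUMNS = ("risk_loving", "altruism", "trust")
_AUX_COLUMNS = ("pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction")

SUBSAMPLES = ("all", "male", "female", "age30_50")

_RANK_TOL = 1e-10


@dataclass
class ModelSpec:
    """Which regression to run: covariate preset, instruments, subsample."""

    outcome: str = "log_earnings"
    focal: str = "height"
    preset: str = PRESET_FULL
    instruments: tuple[str, ...] = ("pgs_height",)
    subsample: str = "all"

    def __post_init__(self) -> None:
        if self.preset not in (PRESET_MINIMAL, PRESET_BENCHMARK, PRESET_FULL):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.subsample not in SUBSAMPLES:
            raise ValueError(f"unknown subsample {self.subsample!r}")
        if self.focal in self.instruments:
            raise ValueError("focal regressor cannot be its own instrument")


@dataclass
class RegressionFit:
    """A least-squares fit: coefficient table, R-squared and residuals."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    n: int
    df_resid: int
    resid: np.ndarray
    colnames: list[str]
    rss: float

    def coef(self, name: str) -> float:
        return float(self.params[name])


@dataclass
class SarganResult:
    statistic: float | None
    df: int
    pvalue: float | None
    applicable: bool


@dataclass
class IVFit:
    """2SLS result with first stage, excluded-instrument F and Sargan."""

    second_stage: RegressionFit
    first_stage: RegressionFit
    f_excluded: float
    f_pvalue: float
    n_instruments: int
    sargan_result: SarganResult
    n: int
    instrument_names: list[str] = field(default_factory=list)


def apply_subsample(df: pd.DataFrame, subsample: str) -> pd.DataFrame:
    if subsample == "all":
        return df
    if subsample == "male":
        return df.loc[df["male"] == 1]
    if subsample == "female":
        return df.loc[df["male"] == 0]
    if subsample == "age30_50":
        return df.loc[(df["age"] >= 30) & (df["age"] <= 50)]
    raise ValueError(f"unknown subsample {subsample!r}")


def build_design(
    pheno: PhenotypeTable | pd.DataFrame,
    spec: ModelSpec,
    include_focal: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble the outcome vector and design matrix for a preset.

    Always includes an intercept and the age-squared term.  Province
    enters as indicators with the most frequent province dropped; the 42
    ancestry proportions enter with the largest-mean component dropped to
    break the sum-to-one collinearity.  Columns that are constant within
    the selected subsample (e.g. ``male`` in a single-sex fit) are
    removed.  A rank-deficient result raises with the dependent columns
    named.
    """
    df = pheno.table if isinstance(pheno, PhenotypeTable) else pheno
    df = apply_subsample(df, spec.subsample)
    if spec.outcome not in df.columns:
        raise KeyError(f"outcome column {spec.outcome!r} absent")

    parts: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    parts["male"] = df["male"].to_numpy(dtype=float)
    parts["age"] = df["age"].to_numpy(dtype=float)
    parts["age_sq"] = parts["age"] ** 2

    if spec.preset in (PRESET_BENCHMARK, PRESET_FULL):
        parts["schooling"] = df["schooling"].to_numpy(dtype=float)
        counts = df["province"].value_counts()
        for prov in sorted(counts.index):
            if prov == counts.idxmax():
                continue
            parts[f"province_{prov}"] = (df["province"] == prov).to_numpy(float)
        anc_cols = [c for c in df.columns if c.startswith("anc_")]
        drop_anc = df[anc_cols].mean().idxmax()
        for c in anc_cols:
            if c != drop_anc:
                parts[c] = df[c].to_numpy(dtype=float)

    if spec.preset == PRESET_FULL:
        for c in (*_PREFERENCE_COLUMNS, *_AUX_COLUMNS):
            parts[c] = df[c].to_numpy(dtype=float)

    if include_focal:
        parts[spec.focal] = df[spec.focal].to_numpy(dtype=float)

    X = pd.DataFrame(parts, index=df.index)
    constant = [
        c for c in X.columns
        if c != "intercept" and np.ptp(X[c].to_numpy()) == 0.0
    ]
    if constant:
        X = X.drop(columns=constant)

    _check_rank(X.to_numpy(), list(X.columns))
    y = df[spec.outcome].to_numpy(dtype=float)
    return y, X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > _RANK_TOL * diag.max()).sum()) if diag.max() > 0 else 0
    if rank < X.shape[1]:
        dependent = [names[i] for i in piv[rank:]]
        raise ValueError(f"design matrix rank deficient; dependent columns: {dependent}")


def fit_ols(y: np.ndarray, X: pd.DataFrame | np.ndarray) -> RegressionFit:
    """Least squares via QR with classical (homoskedastic) inference."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = Xv.shape
    if n <= k:
        raise ValueError("more columns than observations")

    Q, R = np.linalg.qr(Xv)
    diag = np.abs(np.diag(R))
    if diag.max() == 0 or diag.min() <= _RANK_TOL * diag.max():
        _check_rank(Xv, names)  # raises with dependent columns named
    beta = linalg.solve_triangular(R, Q.T @ y)
    resid = y - Xv @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2 = rss / df_resid
    Rinv = linalg.solve_triangular(R, np.eye(k))
    cov = sigma2 * (Rinv @ Rinv.T)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum()) if "intercept" in names else float(y @ y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return RegressionFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        r2=r2,
        n=n,
        df_resid=df_resid,
        resid=resid,
        colnames=names,
        rss=rss,
    )


def fit_2sls(
    y: np.ndarray,
    focal: np.ndarray,
    Z: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    focal_name: str = "height",
) -> IVFit:
    """Two-stage least squares with a single endogenous regressor.

    Stage one regresses the focal variable on instruments plus exogenous
    covariates; stage two regresses the outcome on the fitted focal value
    and the covariates.  Standard errors are rebuilt from the structural
    residual.  The excluded-instrument F comes from the nested stage-one
    comparison; the Sargan statistic is computed when over-identified.
    """
    z_names = list(Z.columns) if isinstance(Z, pd.DataFrame) else [
        f"z{i}" for i in range(np.asarray(Z).shape[1])
    ]
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Zv = np.asarray(Z, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Zv.ndim == 1:
        Zv = Zv[:, None]
    y = np.asarray(y, dtype=float)
    focal = np.asarray(focal, dtype=float)
    n = len(y)
    q = Zv.shape[1]
    if q < 1:
        raise ValueError("at least one instrument is required")

    # stage 1 and its nested (instrument-free) comparison
    W1 = pd.DataFrame(
        np.column_stack([Zv, Xv]), columns=z_names + x_names
    )
    stage1 = fit_ols(focal, W1)
    restricted = fit_ols(focal, pd.DataFrame(Xv, columns=x_names))
    if stage1.rss <= 0 or restricted.rss - stage1.rss < 0:
        raise ValueError("degenerate first stage")
    f_excluded = ((restricted.rss - stage1.rss) / q) / (stage1.rss / stage1.df_resid)
    if not np.isfinite(f_excluded) or f_excluded <= _RANK_TOL:
        raise ValueError("weak design: instruments carry no partial variance")
    f_pvalue = float(stats.f.sf(f_excluded, q, stage1.df_resid))

    fitted_focal = focal - stage1.resid
    W2 = pd.DataFrame(
        np.column_stack([fitted_focal, Xv]), columns=[focal_name] + x_names
    )
    plugin = fit_ols(y, W2)
    beta = plugin.params.to_numpy()

    # structural residual uses the observed focal regressor
    struct_resid = y - beta[0] * focal - Xv @ beta[1:]
    rss = float(struct_resid @ struct_resid)
    k = W2.shape[1]
    df_resid = n - k
    sigma2 = rss / df_resid
    W2v = W2.to_numpy()
    WtW_inv = np.linalg.inv(W2v.T @ W2v)
    bse = np.sqrt(sigma2 * np.diag(WtW_inv))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    second = RegressionFit(
        params=pd.Series(beta, index=W2.columns),
        bse=pd.Series(bse, index=W2.columns),
        tvalues=pd.Series(tvals, index=W2.columns),
        pvalues=pd.Series(pvals, index=W2.columns),
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        n=n,
        df_resid=df_resid,
        resid=struct_resid,
        colnames=list(W2.columns),
        rss=rss,
    )

    if q >= 2:
        aux = fit_ols(
            struct_resid,
            pd.DataFrame(np.column_stack([Zv, Xv]), columns=z_names + x_names),
        )
        statistic = n * aux.r2
        df = q - 1
        sargan_res = SarganResult(
            statistic=float(statistic),
            df=df,
            pvalue=float(stats.chi2.sf(statistic, df)),
            applicable=True,
        )
    else:
        sargan_res = SarganResult(statistic=None, df=0, pvalue=None, applicable=False)

    return IVFit(
        second_stage=second,
        first_stage=stage1,
        f_excluded=float(f_excluded),
        f_pvalue=f_pvalue,
        n_instruments=q,
        sargan_result=sargan_res,
        n=n,
        instrument_names=z_names,
    )


def first_stage_F(fit: IVFit) -> tuple[float, float]:
    """Excluded-instrument F statistic and p-value of a fitted IV model."""
    return fit.f_excluded, fit.f_pvalue


def sargan(fit: IVFit) -> SarganResult:
    """Sargan overidentification result; flagged not-applicable when just-identified."""
    return fit.sargan_result


def fit_model(
    pheno: PhenotypeTable | pd.DataFrame,
    spec: ModelSpec,
    method: str = "ols",
    quadratic_instrument: bool = False,
) -> RegressionFit | IVFit:
    """Convenience wrapper: build the design for a spec and fit it.

    The phenotype table must already carry a ``pgs_height`` column when
    ``method='2sls'``.
    """
    df = pheno.table if isinstance(pheno, PhenotypeTable) else pheno
    df = apply_subsample(df, spec.subsample)
    flat = ModelSpec(
        outcome=spec.outcome, focal=spec.focal, preset=spec.preset,
        instruments=spec.instruments, subsample="all",
    )
    y, X = build_design(df, flat, include_focal=(method == "ols"))
    if method == "ols":
        return fit_ols(y, X)
    if method != "2sls":
        raise ValueError(f"unknown method {method!r}")
    focal = df[spec.focal].to_numpy(dtype=float)
    pgs = df["pgs_height"].to_numpy(dtype=float)
    cols = {"pgs_height": pgs}
    if quadratic_instrument or "pgs_height_sq" in spec.instruments:
        cols["pgs_height_sq"] = (pgs - pgs.mean()) ** 2
    Z = pd.DataFrame(cols, index=df.index)
    return fit_2sls(y, focal, Z, X, focal_name=spec.focal)
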