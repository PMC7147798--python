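"""Synthetic cohort generator for the height-earnings MR analysis.

The real study population is a proprietary direct-to-consumer genotyping
cohort, so every moment the analysis depends on is emulated here from its
published summary statistics:

* 697 independent height SNPs in Hardy-Weinberg equilibrium with allele
  frequencies uniform on a configurable range;
* a weighted polygenic score (PGS) whose population mean and standard
  deviation match the cohort's printed values (-0.598 / 0.446), obtained
  by an affine recalibration of randomly drawn per-SNP weights;
* adult height with ~80% of its variance genetic, of which the scored
  PGS explains the share implied by the first-stage coefficient;
* a single latent "early-life endowment" confounder that loads on
  height, on the risk-loving and altruism preference scores, and on log
  earnings, sized analytically so the benchmark and full-covariate OLS
  height coefficients have the targeted expectations while the genetic
  instrument stays clean (the confounder is independent of all
  genotypes);
* a Mincer-style log-earnings equation (concave age profile, schooling,
  gender, preference and auxiliary-PGS effects) on top of the true
  causal height effect;
* exact-count planting of ineligible records (under-16, over-60,
  student) so the eligibility filter deterministically keeps 3,427 of
  3,600, of exact male counts among the eligible, and of the prime-age
  (30-50) subsample size.

Everything latent is retained in a :class:`TruthRecord` so estimator
consistency and omitted-variable bias can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import (
    ANCESTRY_COLUMNS,
    DosageMatrix,
    PhenotypeTable,
    WeightTable,
)

AUX_PGS_COLUMNS = ("pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction")

# non-complementary allele pairs, so no strand-ambiguity warnings arise
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass
class SimConfig:
    """All knobs of the data-generating process.

    Defaults reproduce the study conditions: cohort moments, the
    first-stage coefficient, the OLS/IV height-coefficient targets and
    the eligibility counts.  ``theta_income`` and ``kappa_risk`` are
    normally left ``None`` and solved by :func:`calibrate` from the OLS
    bias targets via the omitted-variable-bias identity.
    """

    n_raw: int = 3600
    n_snps: int = 697
    allele_freq_range: tuple[float, float] = (0.05, 0.95)

    # structural effects (log-earnings scale unless noted)
    beta_height_true: float = 0.0056      # per cm; pooled IV estimate
    alpha1_pgs: float = 3.9284            # cm per PGS unit, first stage
    pgs_mean_target: float = -0.598
    pgs_sd_target: float = 0.446
    height_mean: float = 169.088          # cm
    height_sd: float = 8.331              # cm
    heritability_total: float = 0.80

    # latent confounder loadings (per confounder s.d.)
    lambda_height: float = 2.0            # cm
    kappa_risk: float | None = None       # preference-score units; solved
    kappa_altruism: float = 0.65
    theta_income: float | None = None     # log earnings; solved

    # calibration targets for the two OLS height coefficients
    ols_benchmark_target: float = 0.0130
    ols_full_target: float = 0.0103

    # Mincer-style earnings equation
    gamma_male: float = 0.0217
    gamma_age: float = 0.2106
    gamma_age2: float = -0.0024
    gamma_school: float = 0.0495
    delta_risk: float = 0.0537
    delta_altruism: float = 0.0012
    delta_trust: float = 0.0010
    delta_aux: tuple[float, ...] = (-0.1092, -0.0052, -0.5255, 0.0148)

    # covariate marginals
    aux_means: tuple[float, ...] = (-0.010, 32.628, 0.074, 0.029)
    aux_sds: tuple[float, ...] = (0.171, 4.233, 0.087, 0.166)
    aux_loadings: tuple[float, ...] = (0.003, -0.113, 0.001, 0.005)
    risk_mean: float = 5.613
    risk_sd: float = 2.136
    altruism_mean: float = 4.862
    altruism_sd: float = 2.490
    trust_mean: float = 5.084
    trust_sd: float = 2.719
    age_mean: float = 30.245
    age_sd: float = 6.667
    schooling_mean: float = 15.604
    schooling_sd: float = 2.237
    log_earnings_mean: float = 11.570
    log_earnings_sd: float = 0.893

    # planted counts among the eligible sample
    n_eligible_male: int = 1922
    n_age_30_50: int = 1843

    # geography / ancestry
    n_provinces: int = 31
    ancestry_top10: tuple[float, ...] = (
        0.5530, 0.2579, 0.0604, 0.0292, 0.0202,
        0.0084, 0.0075, 0.0070, 0.0056, 0.0054,
    )
    ancestry_concentration: float = 1.816

    # planted ineligible records
    n_under16: int = 80
    n_over60: int = 40
    n_students: int = 53

    # direct instrument -> earnings effect (exclusion-restriction violation)
    pleiotropy_effect: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability_total <= 1.0):
            raise ValueError("heritability_total must lie in [0, 1]")
        if min(self.n_under16, self.n_over60, self.n_students) < 0:
            raise ValueError("planted ineligible counts must be nonnegative")
        if self.n_ineligible >= self.n_raw:
            raise ValueError("planted ineligible counts exceed cohort size")
        mean = self.ancestry_mean
        if abs(mean.sum() - 1.0) > 1e-12:
            raise ValueError("ancestry Dirichlet mean does not sum to 1")

    @property
    def n_ineligible(self) -> int:
        return self.n_under16 + self.n_over60 + self.n_students

    @property
    def n_eligible(self) -> int:
        return self.n_raw - self.n_ineligible

    @property
    def ancestry_mean(self) -> np.ndarray:
        top = np.asarray(self.ancestry_top10, dtype=float)
        rest = np.full(42 - len(top), (1.0 - top.sum()) / (42 - len(top)))
        return np.concatenate([top, rest])


@dataclass
class StructuralParams:
    """Variance components and loadings resolved by :func:`calibrate`."""

    sigma_g: float                 # residual polygenic s.d. of height (cm)
    sigma_eps_height: float        # non-genetic, non-confounder height noise (cm)
    theta_income: float            # confounder -> log earnings
    kappa_risk: float              # confounder -> risk-loving
    kappa_altruism: float
    sigma_risk_resid: float
    sigma_altruism_resid: float
    aux_noise_sds: tuple[float, ...]
    sigma_earnings: float          # idiosyncratic log-earnings s.d.
    height_intercept: float        # cm; places E[height] at target
    earnings_intercept: float
    bias_benchmark: float          # analytic OLS bias, benchmark covariates
    bias_full: float               # analytic OLS bias, full covariates


@dataclass
class TruthRecord:
    """Ground truth of one generated cohort: latents plus realized DGP."""

    table: pd.DataFrame            # sample_id, confounder, g_resid, genetic_total
    params: StructuralParams
    config: SimConfig

    @property
    def genetic_total(self) -> np.ndarray:
        return self.table["genetic_total"].to_numpy()


@dataclass
class Cohort:
    """One simulated cohort with full ground truth."""

    weights: WeightTable
    dosages: DosageMatrix
    phenotypes_raw: PhenotypeTable
    truth: TruthRecord


# ---------------------------------------------------------------------------
# analytic moments and calibration


def _joint_covariance(cfg: SimConfig, kappa_risk: float) -> tuple[np.ndarray, list[str]]:
    """Population covariance of [height, risk, altruism, trust, aux1-4, C, S].

    Exact given the linear DGP: the confounder C is standard normal and
    independent of all genotypes; the PGS S enters height with slope
    ``alpha1_pgs`` and each auxiliary PGS with its loading.
    """
    names = ["height", "risk", "altruism", "trust", *AUX_PGS_COLUMNS, "C", "S"]
    k = len(names)
    var_p = cfg.pgs_sd_target**2
    lam, ka = cfg.lambda_height, cfg.kappa_altruism
    cov = np.zeros((k, k))
    idx = {n: i for i, n in enumerate(names)}

    cov[idx["height"], idx["height"]] = cfg.height_sd**2
    cov[idx["risk"], idx["risk"]] = cfg.risk_sd**2
    cov[idx["altruism"], idx["altruism"]] = cfg.altruism_sd**2
    cov[idx["trust"], idx["trust"]] = cfg.trust_sd**2
    cov[idx["C"], idx["C"]] = 1.0
    cov[idx["S"], idx["S"]] = var_p

    cov[idx["height"], idx["risk"]] = lam * kappa_risk
    cov[idx["height"], idx["altruism"]] = lam * ka
    cov[idx["height"], idx["C"]] = lam
    cov[idx["height"], idx["S"]] = cfg.alpha1_pgs * var_p
    cov[idx["risk"], idx["altruism"]] = kappa_risk * ka
    cov[idx["risk"], idx["C"]] = kappa_risk
    cov[idx["altruism"], idx["C"]] = ka

    for a, (col_a, c_a) in enumerate(zip(AUX_PGS_COLUMNS, cfg.aux_loadings)):
        cov[idx["height"], idx[col_a]] = cfg.alpha1_pgs * c_a * var_p
        cov[idx[col_a], idx[col_a]] = cfg.aux_sds[a] ** 2
        cov[idx[col_a], idx["S"]] = c_a * var_p
        for b, (col_b, c_b) in enumerate(zip(AUX_PGS_COLUMNS, cfg.aux_loadings)):
            if b > a:
                cov[idx[col_a], idx[col_b]] = c_a * c_b * var_p

    cov = cov + np.triu(cov, 1).T
    return cov, names


def _ovb_from_moments(
    cfg: SimConfig, kappa_risk: float, theta: float
) -> tuple[float, float]:
    """Analytic omitted-variable bias of the height coefficient.

    Benchmark covariates omit the preference scores and auxiliary PGSs,
    so their earnings effects plus the direct confounder path all load
    onto height through its covariance with each omitted term.  The full
    covariate set leaves only the confounder path, partially absorbed by
    the included (confounder-loaded) preference scores.  Included
    regressors that are independent of height and of the omitted terms
    (age, schooling, gender, province, ancestry) drop out of the
    identity exactly.
    """
    cov, names = _joint_covariance(cfg, kappa_risk)
    idx = {n: i for i, n in enumerate(names)}
    h = idx["height"]

    # benchmark: regression of the omitted systematic part on height alone
    omitted = np.zeros(len(names))
    omitted[idx["C"]] = theta
    omitted[idx["S"]] += cfg.pleiotropy_effect
    omitted[idx["risk"]] = cfg.delta_risk
    omitted[idx["altruism"]] = cfg.delta_altruism
    omitted[idx["trust"]] = cfg.delta_trust
    for col, d in zip(AUX_PGS_COLUMNS, cfg.delta_aux):
        omitted[idx[col]] = d
    bias_benchmark = float(cov[h] @ omitted / cov[h, h])

    # full: preferences and auxiliary PGSs are controlled
    controlled = ["height", "risk", "altruism", "trust", *AUX_PGS_COLUMNS]
    ci = [idx[c] for c in controlled]
    omitted_full = np.zeros(len(names))
    omitted_full[idx["C"]] = theta
    omitted_full[idx["S"]] = cfg.pleiotropy_effect
    gamma = np.linalg.solve(cov[np.ix_(ci, ci)], cov[np.ix_(ci, range(len(names)))] @ omitted_full)
    bias_full = float(gamma[0])
    return bias_benchmark, bias_full


def _theta_given_kappa(cfg: SimConfig, kappa_risk: float) -> float:
    """Invert the benchmark-bias identity for the confounder income loading."""
    var_p = cfg.pgs_sd_target**2
    b_bench = cfg.ols_benchmark_target - cfg.beta_height_true
    aux_term = sum(
        d * cfg.alpha1_pgs * c * var_p
        for d, c in zip(cfg.delta_aux, cfg.aux_loadings)
    )
    pleio_term = cfg.pleiotropy_effect * cfg.alpha1_pgs * var_p
    numer = (
        b_bench * cfg.height_sd**2
        - cfg.lambda_height * (cfg.delta_risk * kappa_risk
                               + cfg.delta_altruism * cfg.kappa_altruism)
        - aux_term
        - pleio_term
    )
    return numer / cfg.lambda_height


def calibrate(cfg: SimConfig) -> StructuralParams:
    """Resolve all variance components analytically from the config.

    Raises ``ValueError`` naming the violated identity when the requested
    moments are jointly infeasible (e.g. confounder loadings exceeding
    the non-genetic height variance, or an omitted-variable-bias target
    no confounder size can reach).
    """
    var_h = cfg.height_sd**2
    var_from_pgs = (cfg.alpha1_pgs * cfg.pgs_sd_target) ** 2
    var_g = cfg.heritability_total * var_h - var_from_pgs
    if var_g < 0:
        raise ValueError(
            "infeasible calibration: PGS variance alpha1^2*sd(PGS)^2 exceeds "
            "heritability_total * Var(height)"
        )
    var_eps_h = (1.0 - cfg.heritability_total) * var_h - cfg.lambda_height**2
    if var_eps_h < 0:
        raise ValueError(
            "infeasible calibration: lambda_height^2 exceeds the "
            "environmental height variance (1 - h2) * Var(height)"
        )
    aux_noise = []
    for sd, c in zip(cfg.aux_sds, cfg.aux_loadings):
        v = sd**2 - (c * cfg.pgs_sd_target) ** 2
        if v < 0:
            raise ValueError(
                "infeasible calibration: auxiliary PGS loading exceeds its "
                "total variance"
            )
        aux_noise.append(np.sqrt(v))

    # confounder loadings: either supplied, or solved so the two OLS bias
    # targets hold exactly in population
    if cfg.theta_income is not None and cfg.kappa_risk is not None:
        theta, kappa_risk = cfg.theta_income, cfg.kappa_risk
    elif cfg.theta_income is None and cfg.kappa_risk is None:
        b_full = cfg.ols_full_target - cfg.beta_height_true

        def gap(kr: float) -> float:
            th = _theta_given_kappa(cfg, kr)
            return _ovb_from_moments(cfg, kr, th)[1] - b_full

        hi = 0.95 * cfg.risk_sd
        try:
            kappa_risk = optimize.brentq(gap, 0.0, hi, xtol=1e-12)
        except ValueError as exc:
            raise ValueError(
                "infeasible calibration: no risk-loving confounder loading "
                "reconciles the benchmark and full OLS bias targets"
            ) from exc
        theta = _theta_given_kappa(cfg, kappa_risk)
    else:
        raise ValueError(
            "theta_income and kappa_risk must be supplied together or both "
            "left to the calibration"
        )

    if kappa_risk**2 > cfg.risk_sd**2 or cfg.kappa_altruism**2 > cfg.altruism_sd**2:
        raise ValueError(
            "infeasible calibration: confounder preference loading exceeds "
            "the preference score variance"
        )
    bias_benchmark, bias_full = _ovb_from_moments(cfg, kappa_risk, theta)

    # idiosyncratic earnings noise closes the log-earnings variance budget
    var_sys = _systematic_earnings_variance(cfg, kappa_risk, theta)
    var_eps_y = cfg.log_earnings_sd**2 - var_sys
    if var_eps_y <= 0:
        raise ValueError(
            "infeasible calibration: systematic earnings variance exceeds "
            "the targeted Var(log earnings)"
        )

    height_intercept = cfg.height_mean - cfg.alpha1_pgs * cfg.pgs_mean_target
    earnings_intercept = cfg.log_earnings_mean - _systematic_earnings_mean(cfg)

    return StructuralParams(
        sigma_g=float(np.sqrt(var_g)),
        sigma_eps_height=float(np.sqrt(var_eps_h)),
        theta_income=float(theta),
        kappa_risk=float(kappa_risk),
        kappa_altruism=cfg.kappa_altruism,
        sigma_risk_resid=float(np.sqrt(cfg.risk_sd**2 - kappa_risk**2)),
        sigma_altruism_resid=float(
            np.sqrt(cfg.altruism_sd**2 - cfg.kappa_altruism**2)
        ),
        aux_noise_sds=tuple(aux_noise),
        sigma_earnings=float(np.sqrt(var_eps_y)),
        height_intercept=float(height_intercept),
        earnings_intercept=float(earnings_intercept),
        bias_benchmark=float(bias_benchmark),
        bias_full=float(bias_full),
    )


def _systematic_earnings_variance(cfg: SimConfig, kappa_risk: float, theta: float) -> float:
    cov, names = _joint_covariance(cfg, kappa_risk)
    idx = {n: i for i, n in enumerate(names)}
    w = np.zeros(len(names))
    w[idx["height"]] = cfg.beta_height_true
    w[idx["risk"]] = cfg.delta_risk
    w[idx["altruism"]] = cfg.delta_altruism
    w[idx["trust"]] = cfg.delta_trust
    for col, d in zip(AUX_PGS_COLUMNS, cfg.delta_aux):
        w[idx[col]] = d
    w[idx["C"]] = theta
    w[idx["S"]] = cfg.pleiotropy_effect
    var = float(w @ cov @ w)
    # independent covariates; age enters quadratically (normal moments)
    mu_a, s2_a = cfg.age_mean, cfg.age_sd**2
    var += (
        cfg.gamma_age**2 * s2_a
        + cfg.gamma_age2**2 * (4 * mu_a**2 * s2_a + 2 * s2_a**2)
        + 2 * cfg.gamma_age * cfg.gamma_age2 * 2 * mu_a * s2_a
    )
    p_male = cfg.n_eligible_male / cfg.n_eligible
    var += cfg.gamma_male**2 * p_male * (1 - p_male)
    var += cfg.gamma_school**2 * cfg.schooling_sd**2
    return var


def _systematic_earnings_mean(cfg: SimConfig) -> float:
    p_male = cfg.n_eligible_male / cfg.n_eligible
    mean = (
        cfg.beta_height_true * cfg.height_mean
        + cfg.gamma_male * p_male
        + cfg.gamma_age * cfg.age_mean
        + cfg.gamma_age2 * (cfg.age_mean**2 + cfg.age_sd**2)
        + cfg.gamma_school * cfg.schooling_mean
        + cfg.delta_risk * cfg.risk_mean
        + cfg.delta_altruism * cfg.altruism_mean
        + cfg.delta_trust * cfg.trust_mean
        + sum(d * m for d, m in zip(cfg.delta_aux, cfg.aux_means))
        + cfg.pleiotropy_effect * cfg.pgs_mean_target
    )
    return mean


def analytic_ovb(cfg: SimConfig, params: StructuralParams | None = None) -> tuple[float, float]:
    """(benchmark, full) OLS height-coefficient bias implied by the DGP."""
    if params is None:
        params = calibrate(cfg)
    return _ovb_from_moments(cfg, params.kappa_risk, params.theta_income)


# ---------------------------------------------------------------------------
# generation


def _calibrated_weights(
    raw: np.ndarray, freqs: np.ndarray, mean_target: float, sd_target: float
) -> np.ndarray:
    """Affine rescaling beta = s*w + d matching the population PGS moments.

    With genotypes Binomial(2, p_j), E[S] = sum(beta_j 2 p_j) and
    Var(S) = sum(beta_j^2 2 p_j (1 - p_j)); the two conditions give a
    quadratic in the scale s whose positive root is taken.
    """
    u = 2.0 * freqs
    v = 2.0 * freqs * (1.0 - freqs)
    w1, usum = float(raw @ u), float(u.sum())
    a = float(raw**2 @ v)
    b = float(raw @ v)
    c = float(v.sum())
    m, var = mean_target, sd_target**2
    # substitute d = (m - s*w1)/usum into the variance condition
    q2 = a - 2 * b * w1 / usum + c * w1**2 / usum**2
    q1 = 2 * b * m / usum - 2 * c * m * w1 / usum**2
    q0 = c * m**2 / usum**2 - var
    disc = q1**2 - 4 * q2 * q0
    if disc < 0 or q2 <= 0:
        raise ValueError("weight recalibration has no real solution")
    s = (-q1 + np.sqrt(disc)) / (2 * q2)
    d = (m - s * w1) / usum
    return s * raw + d


def _draw_eligible_ages(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Eligible ages with an exact planted count in the prime 30-50 band.

    Draws come from a normal truncated to [16, 60]; the 30-50 band is
    filled with exactly ``n_age_30_50`` draws so the prime-age subsample
    size is deterministic.
    """
    mu, sd = cfg.age_mean, cfg.age_sd

    def trunc(lo: float, hi: float, size: int) -> np.ndarray:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)

    n_in = cfg.n_age_30_50
    n_out = cfg.n_eligible - n_in
    inner = trunc(30.0, 50.0, n_in)
    # complement region split by its relative normal mass
    z = stats.norm(mu, sd)
    p_low = z.cdf(30) - z.cdf(16)
    p_high = z.cdf(60) - z.cdf(50)
    n_low = int(rng.binomial(n_out, p_low / (p_low + p_high)))
    outer = np.concatenate(
        [trunc(16.0, 30.0 - 1e-9, n_low), trunc(50.0 + 1e-9, 60.0, n_out - n_low)]
    )
    ages = np.concatenate([inner, outer])
    return rng.permutation(ages)


def generate(cfg: SimConfig, seed: int | None = None) -> Cohort:
    """Draw one cohort: weights, genotypes, phenotypes and ground truth."""
    params = calibrate(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, j = cfg.n_raw, cfg.n_snps

    # --- genotypes and the scored weights
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=j)
    raw_w = rng.standard_normal(j)
    betas = _calibrated_weights(raw_w, freqs, cfg.pgs_mean_target, cfg.pgs_sd_target)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    genotypes = rng.binomial(2, freqs, size=(n, j)).astype(float)
    score = genotypes @ betas

    weights = WeightTable(
        pd.DataFrame(
            {
                "snp_id": [f"rs{1_000_000 + 7 * k}" for k in range(j)],
                "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
                "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
                "beta": betas,
            }
        )
    )
    sample_ids = np.array([f"S{k:04d}" for k in range(n)])
    dosages = DosageMatrix(
        sample_ids=sample_ids,
        snp_ids=weights.snp_ids.copy(),
        dosages=genotypes,
        flipped=np.zeros(j, dtype=bool),
    )

    # --- latent structure and height
    confounder = rng.standard_normal(n)
    g_resid = params.sigma_g * rng.standard_normal(n)
    eps_h = params.sigma_eps_height * rng.standard_normal(n)
    genetic_total = cfg.alpha1_pgs * score + g_resid
    height = (
        params.height_intercept
        + genetic_total
        + cfg.lambda_height * confounder
        + eps_h
    )

    # --- preferences and auxiliary polygenic scores
    risk = cfg.risk_mean + params.kappa_risk * confounder + \
        params.sigma_risk_resid * rng.standard_normal(n)
    altruism = cfg.altruism_mean + params.kappa_altruism * confounder + \
        params.sigma_altruism_resid * rng.standard_normal(n)
    trust = cfg.trust_mean + cfg.trust_sd * rng.standard_normal(n)
    aux = {}
    centered_score = score - cfg.pgs_mean_target
    for col, m, c, s_noise in zip(
        AUX_PGS_COLUMNS, cfg.aux_means, cfg.aux_loadings, params.aux_noise_sds
    ):
        aux[col] = m + c * centered_score + s_noise * rng.standard_normal(n)

    # --- demographics with planted eligibility structure
    age = np.empty(n)
    student = np.zeros(n, dtype=int)
    male = np.empty(n, dtype=int)

    elig_slots = np.arange(cfg.n_eligible)
    age[: cfg.n_eligible] = _draw_eligible_ages(cfg, rng)
    k0 = cfg.n_eligible
    age[k0 : k0 + cfg.n_under16] = rng.uniform(13.0, 16.0 - 1e-6, cfg.n_under16)
    k0 += cfg.n_under16
    age[k0 : k0 + cfg.n_over60] = rng.uniform(61.0, 70.0, cfg.n_over60)
    k0 += cfg.n_over60
    age[k0:] = stats.truncnorm.rvs(
        (16 - cfg.age_mean) / cfg.age_sd,
        (60 - cfg.age_mean) / cfg.age_sd,
        loc=cfg.age_mean, scale=cfg.age_sd,
        size=cfg.n_students, random_state=rng,
    )
    student[k0:] = 1

    male_elig = np.zeros(cfg.n_eligible, dtype=int)
    male_elig[rng.choice(elig_slots, cfg.n_eligible_male, replace=False)] = 1
    male[: cfg.n_eligible] = male_elig
    p_male = cfg.n_eligible_male / cfg.n_eligible
    male[cfg.n_eligible :] = rng.binomial(1, p_male, cfg.n_ineligible)

    schooling = cfg.schooling_mean + cfg.schooling_sd * rng.standard_normal(n)
    province_weights = 1.0 / np.arange(2, cfg.n_provinces + 2)
    province = rng.choice(
        cfg.n_provinces, size=n, p=province_weights / province_weights.sum()
    )
    ancestry = rng.dirichlet(
        cfg.ancestry_concentration * cfg.ancestry_mean, size=n
    )

    # --- earnings
    log_earnings = (
        params.earnings_intercept
        + cfg.beta_height_true * height
        + cfg.gamma_male * male
        + cfg.gamma_age * age
        + cfg.gamma_age2 * age**2
        + cfg.gamma_school * schooling
        + cfg.delta_risk * risk
        + cfg.delta_altruism * altruism
        + cfg.delta_trust * trust
        + sum(d * aux[col] for d, col in zip(cfg.delta_aux, AUX_PGS_COLUMNS))
        + params.theta_income * confounder
        + cfg.pleiotropy_effect * score
        + params.sigma_earnings * rng.standard_normal(n)
    )

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "earnings": np.exp(log_earnings),
            "age": age,
            "male": male,
            "schooling": schooling,
            "height": height,
            "risk_loving": risk,
            "altruism": altruism,
            "trust": trust,
            **aux,
            "province": province,
            "student": student,
        }
    )
    for col, vals in zip(ANCESTRY_COLUMNS, ancestry.T):
        pheno[col] = vals

    # interleave eligible and planted rows
    order = rng.permutation(n)
    pheno = pheno.iloc[order].reset_index(drop=True)
    dosages = DosageMatrix(
        sample_ids=sample_ids[order],
        snp_ids=dosages.snp_ids,
        dosages=genotypes[order],
        flipped=dosages.flipped,
    )
    truth = TruthRecord(
        table=pd.DataFrame(
            {
                "sample_id": sample_ids[order],
                "confounder": confounder[order],
                "g_resid": g_resid[order],
                "genetic_total": genetic_total[order],
                "pgs": score[order],
            }
        ),
        params=params,
        config=dataclasses.replace(cfg),
    )
    return Cohort(
        weights=weights,
        dosages=dosages,
        phenotypes_raw=PhenotypeTable(pheno),
        truth=truth,
    )


def filter_eligible(raw: PhenotypeTable) -> PhenotypeTable:
    """Apply the eligibility filter: keep 16 <= age <= 60 non-students.

    Exclusion counts (by reason, with under-16 taking precedence over
    over-60 over student) are attached to the returned table.
    """
    t = raw.table
    under = t["age"] < 16
    over = (t["age"] > 60) & ~under
    stud = (t["student"] == 1) & ~under & ~over
    keep = ~(under | over | stud)
    counts = {
        "under_16": int(under.sum()),
        "over_60": int(over.sum()),
        "student": int(stud.sum()),
    }
    out = PhenotypeTable(
        t.loc[keep].reset_index(drop=True).copy(),
        n_dropped_nonpositive=raw.n_dropped_nonpositive,
    )
    out.exclusion_counts = counts
    return out
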