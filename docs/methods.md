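# Methods

This document records the statistical model, every calibration identity
used by the synthetic cohort generator, the numerical choices of the
estimators, and the known limitations.

## 1. The estimation problem

The target is the causal effect of adult height on earnings in the
wage equation

```
log(Y_i) = β0 + β1·H_i + X_i'β2 + u_i                 (structural)
H_i      = α0 + α1·S_i + X_i'α2 + v_i                 (first stage)
S_i      = Σ_j  β_j · d_ij                            (polygenic score)
```

where `H` is height in cm, `S` the height polygenic score (PGS) over
697 SNPs with per-allele weights `β_j` and effect-allele dosages
`d_ij ∈ [0,2]`, and `X` a covariate set. OLS of the structural equation
is biased when unobserved early-life endowments raise both height and
earnings (`Cov(H,u) ≠ 0`); because genotypes are fixed at conception,
`S` is a candidate instrument. Three covariate presets are used:

* **minimal** — intercept, gender, age, age²;
* **benchmark** — minimal + schooling, province fixed effects (modal
  province dropped), 42 ancestry proportions (largest-mean component
  dropped to break the sum-to-one collinearity);
* **full** — benchmark + three preference scores (risk-loving,
  altruism, trust) + four auxiliary polygenic scores (cognitive
  performance, depression, delay discounting, age at first birth).

Diagnostics: the excluded-instrument first-stage F (weak-instrument
rule of thumb F ≥ 10), a balance table across above/below-mean PGS
halves (Welch t), the reduced form of log earnings on the score with
height excluded, and — adding the centred squared score as a second
instrument — the Sargan overidentification statistic.

## 2. Synthetic data-generating process

The original cohort is proprietary, so all analyses run on a synthetic
cohort whose every analysis-relevant moment is planted. One draw of
`generate(cfg, seed)` proceeds as follows (all draws from one
`numpy.random.Generator`; `C_i ~ N(0,1)` is the latent early-life
confounder, independent of all genotypes).

1. **Genotypes.** Allele frequencies `p_j ~ U(0.05, 0.95)`, genotypes
   `d_ij ~ Binomial(2, p_j)` (independent SNPs, Hardy–Weinberg).
2. **Weights.** Raw weights `w_j ~ N(0,1)` are affinely recalibrated,
   `β_j = s·w_j + δ`, so the *population* score moments hit the
   published values (mean −0.598, s.d. 0.446); see §3.1.
3. **Height.**
   `H_i = μ_H − α1·E[S] + α1·S_i + g_i + λ·C_i + ε_i` with
   `g_i ~ N(0, σ_g²)` the unscored polygenic residual and
   `ε_i ~ N(0, σ_ε²)`; σ_g and σ_ε close the published variance
   decomposition (§3.2).
4. **Preferences and auxiliary PGSs.** Risk-loving and altruism load on
   `C` (`κ_r`, `κ_a`); trust is independent noise; each auxiliary PGS
   is `m_k + c_k·(S_i − E[S]) + noise`, so it correlates weakly with
   the height score but not with `C`.
5. **Demographics.** Ages for the eligible block are drawn from
   `N(30.245, 6.667²)` truncated to [16, 60], with *exactly* 1,843
   draws planted in [30, 50]; exactly 80 under-16, 40 over-60 and 53
   student records are planted so the eligibility filter
   (16 ≤ age ≤ 60, non-student) keeps exactly 3,427 of 3,600; exactly
   1,922 of the eligible are male. Provinces follow a Zipf-like
   distribution over 31 categories; ancestry proportions are
   `Dirichlet(c·m)` with mean vector `m` matching the published top-10
   components (Northern Han 0.5530, …) and concentration c = 1.816.
6. **Earnings.** A Mincer-style equation
   `log Y = const + β1·H + γ_m·male + γ_a·age + γ_a2·age² + γ_s·school
   + δ'·(preferences, aux PGSs) + θ·C + p·S + σ_y·noise`,
   with `β1 = 0.0056` (the planted causal effect), `θ` the confounder's
   income loading, and `p` (`pleiotropy_effect`, default 0) a direct
   score→earnings effect used to plant exclusion-restriction
   violations. σ_y closes the published Var(log Y) budget.

Every latent component (C, g, total genetic value, S) is retained in a
`TruthRecord`, so estimator consistency and omitted-variable bias are
testable against ground truth.

## 3. Calibration identities

All identities are solved in `calibrate()`; infeasible combinations
raise `ValueError` naming the violated identity.

### 3.1 Score moments

With `d_j ~ Binomial(2, p_j)`, `E[S] = Σ β_j·2p_j` and
`Var(S) = Σ β_j²·2p_j(1−p_j)`. Substituting `β_j = s·w_j + δ` and the
mean condition `δ = (m − s·Σw_j·2p_j)/Σ2p_j` into the variance
condition yields a quadratic in `s`; the positive root is used. This
pins the population score moments for any drawn `w, p`.

### 3.2 Height variance decomposition

Writing h² = 0.80 for total heritability and σ_H = 8.331:

```
σ_g² = h²·σ_H² − (α1·σ_S)²          (unscored polygenic variance)
σ_ε² = (1−h²)·σ_H² − λ²             (non-genetic, non-confounder noise)
```

with α1 = 3.9284, σ_S = 0.446, λ = 2.0 cm per confounder s.d. The
implied population R² of height on the score is
`(α1·σ_S)²/σ_H² ≈ 0.0442`, slightly below the published marginal 0.0459
— the published trio (α1, σ_S, σ_H) is internally inconsistent with it,
and the calibration prioritizes the trio.

### 3.3 Confounder loadings from the OLS bias targets

The two published OLS height coefficients (benchmark 0.0130, full
0.0103) exceed the causal 0.0056; the gaps are planted *exactly* via
the omitted-variable-bias identity. For any candidate (κ_r, θ) the
population covariance matrix Σ of
`[H, risk, altruism, trust, aux₁..₄, C, S]` is exact under the linear
DGP, and

* benchmark bias = `Cov(H, ω)/Var(H)` where ω is the omitted systematic
  earnings part (θ·C + p·S + preference and aux-PGS effects); included
  benchmark covariates are independent of both H and ω, so they drop
  out exactly;
* full bias = the first element of `Σ_RR⁻¹ Cov(R, θ·C + p·S)` with R =
  [H, preferences, aux PGSs] the included regressors.

θ is eliminated analytically via the benchmark identity, and κ_r is
solved by Brent root-finding on the full-bias identity. Defaults give
θ ≈ 0.208 and κ_r ≈ 0.908. Residual preference variances
(σ² − κ²) and the idiosyncratic earnings variance
(`Var(log Y) − systematic`) must stay positive, else calibration
raises.

### 3.4 Parameter provenance

| parameter | default | origin |
|---|---|---|
| n_raw / eligible / male / prime-age | 3600 / 3427 / 1922 / 1843 | published counts |
| n_snps | 697 | published |
| β1 (causal) | 0.0056 | published 2SLS |
| α1 | 3.9284 | published first stage |
| PGS mean / s.d. | −0.598 / 0.446 | published Table 1 |
| height mean / s.d. | 169.088 / 8.331 | published Table 1 |
| h² | 0.80 | published narrative |
| OLS targets | 0.0130 / 0.0103 | published Table 5 |
| λ (C→height) | 2.0 cm | chosen within the (1−h²)σ_H² budget |
| κ_a (C→altruism) | 0.65 | chosen; κ_r, θ solved from OLS targets |
| Mincer γ, δ coefficients | Table-7 2SLS column | published |
| aux-PGS loadings on S | (0.003, −0.113, 0.001, 0.005) | sized from the published balance-table differences, signed per the published trait panel (the two published tables are mutually inconsistent in magnitude; the balance behaviour is the acceptance-relevant one) |
| preference / aux moments | Table-1 values | published |
| ancestry top-10 mean, concentration | Table-3 values, 1.816 | published / fitted |
| age distribution | N(30.245, 6.667²) truncated [16,60] | published moments (a uniform age law would contradict the published s.d.) |

## 4. Numerical choices

* **OLS** via thin-QR; coefficients from back-substitution; classical
  homoskedastic covariance σ̂²(R⁻¹R⁻ᵀ); centred R² when an intercept is
  present. Rank is checked with pivoted QR (relative tolerance 1e-10);
  deficiency raises with the dependent columns named.
* **2SLS** fits stage one on [Z, X]; stage two on [Ĥ, X]. Standard
  errors are rebuilt from the *structural* residual
  `y − β̂1·H_observed − Xγ̂` (not the stage-two plug-in residual).
* **Excluded-instrument F** from the nested stage-one RSS comparison;
  with one instrument it equals the squared first-stage t.
* **Sargan** = n·R² of the structural residuals regressed on [Z, X];
  χ² with (#instruments − 1) df; flagged not-applicable when
  just-identified. The quadratic instrument is centred before squaring
  for conditioning (the spanned space is unchanged).
* **Seeding**: a master seed spawns per-stage/per-replicate
  `SeedSequence` substreams, so runs are bit-reproducible and adding a
  stage never perturbs earlier draws.
* **Missing dosages** are imputed with the SNP's observed-sample mean
  (score-mean-preserving); per-person imputation counts are reported.

## 5. Known limitations

* **No linkage disequilibrium.** SNPs are independent; fine for the
  moments used here, wrong for LD-aware analyses.
* **Preference scores are continuous Gaussians**, not the survey's
  1–10 integer scale; clipping/discretizing would distort the
  analytically planted covariances.
* **Ages** use a truncated normal matched to the published mean/s.d.,
  not the survey's empirical age histogram.
* **Attenuation ordering is capped near 73%.** The published full-OLS
  minus 2SLS gap (0.0047) is smaller than the per-replicate sampling
  s.d. of the IV−OLS difference (≈ 0.007, pinned by the published
  instrument strength and earnings noise — the published IV standard
  error is 0.0107), so `P(β̂_IV < β̂_OLS) ≈ Φ(0.0047/0.007) ≈ 0.73`.
  No generator matching the published quantities can reach the
  sometimes-quoted "95% of replicates".
* **The quadratic-score Sargan test has zero power against linear
  pleiotropy.** With instruments [S, (S−S̄)²] and a linear first stage,
  a direct earnings effect p·S moves *every* instrument's Wald ratio to
  the same value β1 + p/α1, so the overidentifying restriction remains
  satisfied: the planted effect is absorbed into the estimand rather
  than detected (verified: the Monte-Carlo IV mean tracks β1 + p/α1 to
  within MC error while the Sargan rejection rate stays at its null
  level). This is a genuine weakness of functionally dependent
  instruments in Mendelian randomization, not an implementation
  artifact; the test retains power only against *nonlinear* direct
  effects.
* **Scores are reported on the raw weighted-sum scale** (the published
  mean −0.598 lives on that scale); `standardize=True` is available but
  not the default.
* **Small-sample Sargan calibration** degrades below n ≈ 1000 (the χ²₁
  approximation over-rejects); calibration checks are run at the study
  size n = 3,427.
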