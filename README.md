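# polyiv

One-sample Mendelian-randomization analysis of the height–earnings
premium, with a fully calibrated synthetic cohort.

Tall people earn more. Is that because height itself is rewarded, or
because early-life conditions (nutrition, family environment) raise both
adult height and adult earnings? `polyiv` implements the
instrumental-variable strategy used to separate the two: a polygenic
score (PGS) for height — a weighted sum of allele dosages over 697
independent height-associated SNPs — is assigned at conception and is
therefore unconfounded by later environment, so it can instrument
observed height in a wage regression.

The original analysis was run on a proprietary genotyped cohort
(n = 3,427 working-age adults after filtering a 3,600-person panel).
Because those individual records cannot be shared, `polyiv` ships a
**calibrated synthetic cohort generator**: every moment the analysis
depends on — cohort demographics, the PGS distribution, the first-stage
coefficient, the confounded OLS and the causal 2SLS height coefficients,
the ancestry composition — is planted analytically so the full pipeline
reproduces the published quantities in expectation, while complete
ground truth (the latent confounder, the total genetic value, the true
causal effect) is retained for verification. See
[docs/methods.md](docs/methods.md) for the model and every calibration
identity.

What the package provides:

* **`polyiv.io_formats`** — strict readers/writers for PGS-Catalog-style
  scoring files, VCF or tabular dosages (with effect-allele alignment
  and flip handling), and the phenotype/covariate table with 42 ancestry
  proportions.
* **`polyiv.scoring`** — the polygenic score (Σⱼ βⱼ · dosageᵢⱼ) with
  mean-imputation of missing dosages, the above/below-mean split, and
  the score density.
* **`polyiv.estimators`** — OLS and 2SLS from first principles (QR
  decomposition, classical standard errors, excluded-instrument
  first-stage F, Sargan overidentification statistic), plus the nested
  covariate presets (minimal / benchmark / full) and subsamples.
* **`polyiv.validity`** — the instrument-validity battery: balance
  table across PGS halves, reduced form, OLS–IV attenuation comparison,
  and the quadratic-score overidentification test.
* **`polyiv.cohort`** — the synthetic generator (`SimConfig`,
  `generate`, `calibrate`, `analytic_ovb`) with exact-count planting of
  the eligibility structure (80 under-16, 40 over-60, 53 students;
  1,922 eligible men; 1,843 aged 30–50).
* **`polyiv.replication`** — one-command reproduction of the whole
  study on a simulated cohort, and a Monte-Carlo runner that compares
  replicate distributions against the generator's ground truth.

## Worked example

Reproduce the full study on one simulated cohort (defaults are the
study conditions; takes a few seconds):

```console
$ polyiv run --seed 1 --out study/
{
  "config_hash": "e99ef8664ae66b6c",
  "master_seed": 1,
  ...
  "n_raw": 3600,
  "n_eligible": 3427,
  "exclusion_counts": {
    "under_16": 80,
    "over_60": 40,
    "student": 53
  }
}
```

`study/` now holds the cohort artifacts (`weights.tsv`,
`genotypes.vcf`, `phenotypes_raw.tsv`, `truth.tsv`) and the table
analogues. The OLS table shows the confounded height premium
(benchmark ≈ 1.3%/cm, shrinking when preference and auxiliary-PGS
controls are added):

```console
$ head -3 study/table5_ols.tsv
model	height_coef	height_se	height_p	r2	n
benchmark:all	0.012558	0.001517	0.0	0.277296	3427
full:all	0.009734	0.001463	0.0	0.340278	3427
```

The 2SLS table instruments height with the PGS; the estimate drops to
the planted causal effect (0.0056) and loses significance, while the
first stage is strong:

```console
$ head -2 study/table7_2sls.tsv
model	height_coef	height_se	height_p	first_stage_pgs	first_stage_pgs_se	first_stage_F	first_stage_F_p	n
all	0.005505	0.006255	0.378899	4.378233	0.314357	193.977713	0.0	3427
```

Individual models and the validity battery are also available directly:

```console
$ polyiv fit --data study --preset benchmark --out ols.tsv
OLS height coefficient 0.0126, R2 0.2773

$ polyiv fit --data study --iv --out iv.tsv
2SLS height coefficient 0.0055, first-stage F 194.0

$ polyiv validate --data study --out validity/
relevance_f_above_10: True
balance_non_height_rejections_5pct: 0
reduced_form_pgs_significant: False
iv_attenuated: True
sargan_reject_5pct: False
```

The balance table illustrates the instrument logic: people above and
below the mean PGS differ in height (by ≈ 2.7 cm in expectation) but in
nothing else:

```console
$ head -4 study/table2_balance.tsv
variable	mean_higher	se_higher	mean_lower	se_lower	difference	t	p	degenerate
log_earnings	11.598175	0.02103	11.576674	0.020093	0.021501	0.739228	0.459819	False
height	170.598641	0.201109	167.514199	0.194592	3.084442	11.022123	0.0	False
age	30.777292	0.155501	30.647235	0.15199	0.130057	0.59812	0.5498	False
```

The same pipeline runs on external data: score any VCF against any
scoring file with `polyiv score --vcf ... --weights ... --out ...`, or
simulate cohorts under modified conditions via a YAML config whose keys
mirror `SimConfig` (e.g. `pleiotropy_effect: 0.1` plants an
exclusion-restriction violation):

```bash
polyiv simulate --config study.yaml --seed 5 --out sim/
polyiv mc --reps 200 --seed 1 --out mc.tsv   # Monte-Carlo vs ground truth
```

## Layout

```
src/polyiv/          library (io_formats, scoring, estimators,
                     validity, cohort, replication, cli)
src/polyiv/data/     bundled synthetic 697-SNP scoring file
tests/               unit, property and acceptance tests
scripts/acceptance.py  headline-quantity JSON report
docs/methods.md      model, calibration identities, limitations
```
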