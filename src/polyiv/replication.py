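"""End-to-end study orchestration and the Monte-Carlo experiment runner.

``run_replication`` executes the whole pipeline on one simulated cohort
— simulate, score, filter, fit every OLS/2SLS model variant and
subsample, run the validity battery — and writes the study's table
analogues as TSV files plus a JSON manifest.  ``run_monte_carlo``
repeats the pipeline over independent cohorts and summarizes the
replicate distribution of every headline quantity against the
generator's ground truth and the analytic omitted-variable-bias oracle.

Seeding: one master seed spawns independent per-replicate substreams
(``numpy.random.SeedSequence``), so runs are reproducible and adding a
stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SimConfig, analytic_ovb, filter_eligible, generate
from .estimators import ModelSpec, fit_model
from .io_formats import DosageMatrix, PhenotypeTable, write_phenotypes, write_vcf, write_weights
from .scoring import compute_pgs, score_density
from .validity import balance_table, reduced_form, trait_panels

logger = logging.getLogger(__name__)

_SUMMARY_VARIABLES = (
    "earnings", "log_earnings", "age", "schooling", "height", "male",
    "pgs_height", "risk_loving", "altruism", "trust",
    "pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction",
)

_OLS_COLUMNS = (
    ("benchmark", "all"), ("full", "all"), ("full", "male"),
    ("full", "female"), ("full", "age30_50"),
)
_IV_COLUMNS = (("all",), ("male",), ("female",), ("age30_50",))


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict
    outputs: dict
    wall_clock: dict
    n_raw: int
    n_eligible: int
    exclusion_counts: dict


def config_hash(cfg: SimConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analytical_sample(cfg: SimConfig, seed: int | None = None):
    """Simulate, score and filter one cohort.

    Returns ``(cohort, pheno, scores)`` where ``pheno`` is the eligible
    analytical sample with the recomputed ``pgs_height`` column attached.
    """
    cohort = generate(cfg, seed=seed)
    scores_raw = compute_pgs(cohort.dosages, cohort.weights)
    raw = cohort.phenotypes_raw.table.copy()
    raw["pgs_height"] = scores_raw.score
    pheno = filter_eligible(
        PhenotypeTable(raw, cohort.phenotypes_raw.n_dropped_nonpositive)
    )
    keep = pheno.table["sample_id"].to_numpy()
    idx = pd.Index(cohort.dosages.sample_ids)
    rows = idx.get_indexer(keep)
    elig_dosages = DosageMatrix(
        sample_ids=keep,
        snp_ids=cohort.dosages.snp_ids,
        dosages=cohort.dosages.dosages[rows],
        flipped=cohort.dosages.flipped,
    )
    scores = compute_pgs(elig_dosages, cohort.weights)
    return cohort, pheno, scores


def _round(df: pd.DataFrame, ndigits: int = 6) -> pd.DataFrame:
    return df.round(ndigits)


def run_replication(
    cfg: SimConfig, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Run the full study on one cohort and write its table analogues."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    (sim_seed,) = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(1)]

    outputs: dict[str, str] = {}
    clocks: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, *a):
                clocks[name] = round(time.perf_counter() - self_.t0, 4)
                if exc_type is not None:
                    logger.error("stage %s failed; removing partial outputs", name)
                    for f in out.glob("*"):
                        f.unlink()
                return False

        return _T()

    with stage("simulate"):
        cohort, pheno, scores = analytical_sample(cfg, seed=sim_seed)
        write_weights(cohort.weights, out / "weights.tsv")
        write_vcf(cohort.dosages, cohort.weights, out / "genotypes.vcf")
        write_phenotypes(cohort.phenotypes_raw, out / "phenotypes_raw.tsv")
        cohort.truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
        outputs.update(
            weights="weights.tsv", genotypes="genotypes.vcf",
            phenotypes_raw="phenotypes_raw.tsv", truth="truth.tsv",
        )
        logger.info(
            "cohort: %d raw -> %d eligible %s",
            cfg.n_raw, pheno.n, pheno.exclusion_counts,
        )

    df = pheno.table

    with stage("summary"):
        rows = [
            {"variable": v, "mean": df[v].mean(), "sd": df[v].std(ddof=1)}
            for v in _SUMMARY_VARIABLES
        ]
        _round(pd.DataFrame(rows)).to_csv(out / "table1_summary.tsv", sep="\t", index=False)
        anc = pheno.ancestry_columns
        anc_stats = df[anc].agg(["mean", "std", "min", "max"]).T.reset_index(names="ancestry")
        _round(anc_stats.sort_values("mean", ascending=False).head(10)).to_csv(
            out / "table3_ancestry.tsv", sep="\t", index=False
        )
        outputs["table1"] = "table1_summary.tsv"
        outputs["table3"] = "table3_ancestry.tsv"

    with stage("balance"):
        bal = balance_table(df, scores)
        _round(bal).to_csv(out / "table2_balance.tsv", sep="\t", index=False)
        outputs["table2"] = "table2_balance.tsv"

    with stage("reduced_form"):
        fits = reduced_form(df, scores)
        rows = []
        for i, f in enumerate(fits, 1):
            rows.append(
                {
                    "specification": i,
                    "pgs_coef": f.coef("pgs_height"),
                    "pgs_se": float(f.bse["pgs_height"]),
                    "pgs_p": float(f.pvalues["pgs_height"]),
                    "r2": f.r2,
                    "n": f.n,
                }
            )
        _round(pd.DataFrame(rows)).to_csv(out / "table4_reduced_form.tsv", sep="\t", index=False)
        outputs["table4"] = "table4_reduced_form.tsv"

    with stage("ols"):
        rows = []
        for preset, sub in _OLS_COLUMNS:
            fit = fit_model(df, ModelSpec(preset=preset, subsample=sub), method="ols")
            rows.append(
                {
                    "model": f"{preset}:{sub}",
                    "height_coef": fit.coef("height"),
                    "height_se": float(fit.bse["height"]),
                    "height_p": float(fit.pvalues["height"]),
                    "r2": fit.r2,
                    "n": fit.n,
                }
            )
        _round(pd.DataFrame(rows)).to_csv(out / "table5_ols.tsv", sep="\t", index=False)
        outputs["table5"] = "table5_ols.tsv"

    with stage("trait_panels"):
        pa, pb = trait_panels(df, scores)
        _round(pa).to_csv(out / "table6_panel_a.tsv", sep="\t", index=False)
        _round(pb).to_csv(out / "table6_panel_b.tsv", sep="\t", index=False)
        outputs["table6a"] = "table6_panel_a.tsv"
        outputs["table6b"] = "table6_panel_b.tsv"

    with stage("2sls"):
        rows = []
        for (sub,) in _IV_COLUMNS:
            fit = fit_model(df, ModelSpec(subsample=sub), method="2sls")
            rows.append(
                {
                    "model": sub,
                    "height_coef": fit.second_stage.coef("height"),
                    "height_se": float(fit.second_stage.bse["height"]),
                    "height_p": float(fit.second_stage.pvalues["height"]),
                    "first_stage_pgs": fit.first_stage.coef("pgs_height"),
                    "first_stage_pgs_se": float(fit.first_stage.bse["pgs_height"]),
                    "first_stage_F": fit.f_excluded,
                    "first_stage_F_p": fit.f_pvalue,
                    "n": fit.n,
                }
            )
        _round(pd.DataFrame(rows)).to_csv(out / "table7_2sls.tsv", sep="\t", index=False)
        outputs["table7"] = "table7_2sls.tsv"

    with stage("overid"):
        rows = []
        for (sub,) in _IV_COLUMNS:
            fit = fit_model(
                df, ModelSpec(subsample=sub), method="2sls", quadratic_instrument=True
            )
            sg = fit.sargan_result
            rows.append(
                {
                    "model": sub,
                    "height_coef": fit.second_stage.coef("height"),
                    "quadratic_first_stage_t": float(
                        fit.first_stage.tvalues["pgs_height_sq"]
                    ),
                    "sargan": sg.statistic,
                    "sargan_df": sg.df,
                    "sargan_p": sg.pvalue,
                    "n": fit.n,
                }
            )
        _round(pd.DataFrame(rows)).to_csv(out / "tableA1_overid.tsv", sep="\t", index=False)
        outputs["tableA1"] = "tableA1_overid.tsv"

    with stage("density"):
        hist, dens = score_density(scores)
        _round(dens).to_csv(out / "fig3_density.tsv", sep="\t", index=False)
        outputs["fig3"] = "fig3_density.tsv"

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        master_seed=master,
        stage_seeds={"simulate": sim_seed},
        outputs=outputs,
        wall_clock=clocks,
        n_raw=cfg.n_raw,
        n_eligible=pheno.n,
        exclusion_counts=pheno.exclusion_counts,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest


def replicate_metrics(cfg: SimConfig, seed: int) -> dict:
    """All headline quantities of one simulated replicate."""
    from scipy import stats as st

    cohort, pheno, scores = analytical_sample(cfg, seed=seed)
    df = pheno.table

    ols_bench = fit_model(df, ModelSpec(preset="benchmark"), method="ols")
    ols_full = fit_model(df, ModelSpec(preset="full"), method="ols")
    iv_full = fit_model(df, ModelSpec(preset="full"), method="2sls")
    overid = fit_model(
        df, ModelSpec(preset="full"), method="2sls", quadratic_instrument=True
    )

    bal = balance_table(df, scores)
    non_height = bal.loc[bal["variable"] != "height"]
    height_row = bal.loc[bal["variable"] == "height"].iloc[0]

    # marginal instrument strength and truth-based heritability check
    truth = cohort.truth.table.set_index("sample_id").loc[df["sample_id"]]
    h = df["height"].to_numpy()
    pgs_r2 = st.pearsonr(scores.score, h)[0] ** 2
    genetic_r2 = st.pearsonr(truth["genetic_total"].to_numpy(), h)[0] ** 2

    return {
        "seed": seed,
        "n": len(df),
        "ols_benchmark": ols_bench.coef("height"),
        "ols_full": ols_full.coef("height"),
        "iv_full": iv_full.second_stage.coef("height"),
        "iv_se": float(iv_full.second_stage.bse["height"]),
        "first_stage_coef": iv_full.first_stage.coef("pgs_height"),
        "first_stage_F": iv_full.f_excluded,
        "sargan_stat": overid.sargan_result.statistic,
        "sargan_p": overid.sargan_result.pvalue,
        "quad_first_stage_t": float(overid.first_stage.tvalues["pgs_height_sq"]),
        "balance_non_height_rejections": int((non_height["p"] < 0.05).sum()),
        "balance_non_height_rows": len(non_height),
        "height_gap": float(height_row["difference"]),
        "iv_lt_ols": bool(
            iv_full.second_stage.coef("height") < ols_full.coef("height")
        ),
        "pgs_r2": pgs_r2,
        "genetic_r2": genetic_r2,
        "pgs_mean": float(scores.score.mean()),
        "pgs_sd": float(scores.score.std(ddof=1)),
        "height_mean": float(h.mean()),
        "height_sd": float(h.std(ddof=1)),
        "northern_han_mean": float(df["anc_northern_han"].mean()),
    }


def run_monte_carlo(
    cfg: SimConfig, n_reps: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the pipeline and summarize against the DGP's ground truth.

    Returns ``(per_replicate, summary)``; the summary holds each
    metric's replicate mean and Monte-Carlo standard error, plus the
    relevant truth references (planted causal effect, analytic OLS
    biases).
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
    rows = [replicate_metrics(cfg, s) for s in rep_seeds]
    per_rep = pd.DataFrame(rows)

    bias_bench, bias_full = analytic_ovb(cfg)
    refs = {
        "ols_benchmark": cfg.beta_height_true + bias_bench,
        "ols_full": cfg.beta_height_true + bias_full,
        "iv_full": cfg.beta_height_true
        + cfg.pleiotropy_effect / cfg.alpha1_pgs,
        "genetic_r2": cfg.heritability_total,
        "pgs_mean": cfg.pgs_mean_target,
        "pgs_sd": cfg.pgs_sd_target,
        "height_mean": cfg.height_mean,
        "height_sd": cfg.height_sd,
        "northern_han_mean": float(cfg.ancestry_mean[0]),
    }
    numeric = per_rep.drop(columns=["seed", "iv_lt_ols"]).astype(float)
    summary = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "mc_se": numeric.std(ddof=1) / np.sqrt(n_reps),
            "truth": pd.Series(refs),
        }
    )
    summary.loc["iv_lt_ols_rate", ["mean", "mc_se"]] = [
        per_rep["iv_lt_ols"].mean(),
        per_rep["iv_lt_ols"].astype(float).std(ddof=1) / np.sqrt(n_reps),
    ]
    return per_rep, summary
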