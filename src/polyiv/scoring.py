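"""Polygenic score computation and descriptive outputs.

The height score of individual i is the weighted allele count
``score_i = sum_j beta_j * dosage_ij`` over the scored SNPs.  Scores are
reported on the raw weighted-sum scale (not standardized): the cohort's
printed mean of -0.598 is on that scale.  Missing dosages are imputed
with the SNP's sample-mean dosage, which leaves the score mean unbiased;
per-person imputation counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_formats import DosageMatrix, WeightTable


@dataclass
class ScoreVector:
    sample_ids: np.ndarray
    score: np.ndarray
    n_imputed: np.ndarray      # per person, count of mean-imputed SNPs
    summary: dict

    def __post_init__(self) -> None:
        if len(self.score) != len(self.sample_ids):
            raise ValueError("score length inconsistent with sample ids")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("non-finite polygenic score")

    def __len__(self) -> int:
        return len(self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pgs_height": self.score,
                "n_imputed": self.n_imputed,
            }
        )


def compute_pgs(
    dosages: DosageMatrix, weights: WeightTable, standardize: bool = False
) -> ScoreVector:
    """Weighted sum of effect-allele dosages over the SNP intersection."""
    wt = pd.Series(weights.betas, index=weights.snp_ids)
    common = [s for s in dosages.snp_ids if s in wt.index]
    if not common:
        raise ValueError("no SNPs shared between dosages and weights")
    cols = [i for i, s in enumerate(dosages.snp_ids) if s in wt.index]
    D = dosages.dosages[:, cols]
    beta = wt.loc[[dosages.snp_ids[i] for i in cols]].to_numpy()

    missing = np.isnan(D)
    n_imputed = missing.sum(axis=1).astype(int)
    if missing.any():
        observed = np.where(missing, 0.0, D)
        counts = (~missing).sum(axis=0)
        # sample-mean dosage per SNP; a fully absent SNP contributes zero
        col_means = np.divide(
            observed.sum(axis=0), counts,
            out=np.zeros(D.shape[1]), where=counts > 0,
        )
        D = np.where(missing, col_means[None, :], D)

    score = D @ beta
    if standardize:
        sd = score.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot standardize a zero-variance score")
        score = (score - score.mean()) / sd
    summary = {
        "mean": float(score.mean()),
        "sd": float(score.std(ddof=1)),
        "min": float(score.min()),
        "max": float(score.max()),
        "n_snps_scored": len(cols),
    }
    return ScoreVector(
        sample_ids=dosages.sample_ids.copy(),
        score=score,
        n_imputed=n_imputed,
        summary=summary,
    )


def split_by_mean(scores: ScoreVector) -> pd.Series:
    """Label each person 'higher' (score above the sample mean) or 'lower'.

    A score exactly at the mean goes to 'lower' (fixed tie rule).
    """
    s = scores.score
    if len(s) < 2:
        raise ValueError("need at least two scores to split")
    if np.ptp(s) == 0:
        raise ValueError("degenerate split: zero-variance scores")
    labels = np.where(s > s.mean(), "higher", "lower")
    return pd.Series(labels, index=pd.Index(scores.sample_ids, name="sample_id"))


def score_density(
    scores: ScoreVector, n_bins: int = 40, n_grid: int = 512
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram and kernel-smoothed density of the score distribution.

    Returns ``(histogram, density)`` tables; the density column is
    renormalized so it integrates to one over its grid by the trapezoid
    rule.
    """
    s = scores.score
    if len(s) < 10:
        raise ValueError("need at least 10 scores for a density")
    counts, edges = np.histogram(s, bins=n_bins, density=True)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": counts}
    )
    kde = gaussian_kde(s)
    bw = kde.factor * s.std(ddof=1)
    grid = np.linspace(s.min() - 4 * bw, s.max() + 4 * bw, n_grid)
    dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return hist, pd.DataFrame({"pgs_height": grid, "density": dens})
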