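"""Small deterministic builders shared by the unit tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from polyiv.io_formats import (
    ANCESTRY_COLUMNS,
    DosageMatrix,
    WeightTable,
)


def make_weight_table(n_snps: int = 4, seed: int = 0) -> WeightTable:
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]
    rows = []
    for k in range(n_snps):
        eff, oth = pairs[k % len(pairs)]
        rows.append(
            {
                "snp_id": f"rs{100 + k}",
                "effect_allele": eff,
                "other_allele": oth,
                "beta": float(rng.normal()),
            }
        )
    return WeightTable(pd.DataFrame(rows))


def make_dosage_matrix(
    weights: WeightTable, n_samples: int = 3, seed: int = 1, with_missing: bool = False
) -> DosageMatrix:
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n_samples, weights.n_snps)).astype(float)
    if with_missing:
        d[0, 0] = np.nan
    return DosageMatrix(
        sample_ids=np.array([f"P{i}" for i in range(n_samples)]),
        snp_ids=weights.snp_ids.copy(),
        dosages=d,
        flipped=np.zeros(weights.n_snps, dtype=bool),
    )


def make_pheno_frame(n: int = 20, seed: int = 2) -> pd.DataFrame:
    """A minimal valid phenotype table with all required columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"P{i}" for i in range(n)],
            "earnings": np.exp(rng.normal(11.5, 0.8, n)),
            "age": rng.uniform(20, 55, n),
            "male": rng.integers(0, 2, n),
            "schooling": rng.normal(15.6, 2.2, n),
            "height": rng.normal(169.0, 8.3, n),
            "risk_loving": rng.normal(5.6, 2.1, n),
            "altruism": rng.normal(4.9, 2.5, n),
            "trust": rng.normal(5.1, 2.7, n),
            "pgs_cognitive": rng.normal(0, 0.17, n),
            "pgs_depression": rng.normal(32.6, 4.2, n),
            "pgs_delay": rng.normal(0.07, 0.09, n),
            "pgs_reproduction": rng.normal(0.03, 0.17, n),
            "province": rng.integers(0, 5, n),
            "student": np.zeros(n, dtype=int),
        }
    )
    anc = rng.dirichlet(np.ones(42), size=n)
    for col, vals in zip(ANCESTRY_COLUMNS, anc.T):
        df[col] = vals
    df["log_earnings"] = np.log(df["earnings"])
    return df
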