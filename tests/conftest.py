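"""Shared fixtures: one default cohort plus the heavy Monte-Carlo runs.

The expensive simulations are session-scoped so the calibration and
property tests share them.  Seeds are fixed constants chosen before any
outcome was inspected; the scaled configuration shrinks the cohort
proportionally for property tests where only the direction of an effect
matters, never for calibration against printed values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyiv.cohort import SimConfig, generate
from polyiv.estimators import ModelSpec, fit_model
from polyiv.replication import analytical_sample, run_monte_carlo
from polyiv.validity import balance_table

MC_SEED = 1234
NULL_BATTERY_SEED = 56789
DEFAULT_COHORT_SEED = 7


def scaled_config(**overrides) -> SimConfig:
    """A ~1/5-size cohort with the same structure for property tests."""
    base = dict(
        n_raw=700, n_snps=120,
        n_under16=8, n_over60=6, n_students=6,
        n_eligible_male=382, n_age_30_50=366,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def make_scaled_config():
    return scaled_config


@pytest.fixture(scope="session")
def default_cohort():
    return generate(SimConfig(), seed=DEFAULT_COHORT_SEED)


@pytest.fixture(scope="session")
def default_sample():
    """(cohort, eligible phenotypes with pgs_height, eligible scores)."""
    return analytical_sample(SimConfig(), seed=DEFAULT_COHORT_SEED)


@pytest.fixture(scope="session")
def mc200():
    """200-replicate Monte-Carlo under the default study conditions."""
    return run_monte_carlo(SimConfig(), 200, seed=MC_SEED)


@pytest.fixture(scope="session")
def null_battery_500():
    """Per-replicate balance rejections and Sargan p over 500 default cohorts.

    Used by the type-I-calibration checks: the DGP's instrument is valid
    (no pleiotropy), so both the non-height balance tests and the
    quadratic-score Sargan test should reject at close to their nominal
    5% level.
    """
    cfg = SimConfig()
    ss = np.random.SeedSequence(NULL_BATTERY_SEED)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(500)]
    rows = []
    for seed in seeds:
        _, pheno, scores = analytical_sample(cfg, seed=seed)
        df = pheno.table
        bal = balance_table(df, scores)
        non_height = bal.loc[bal["variable"] != "height"]
        overid = fit_model(
            df, ModelSpec(preset="full"), method="2sls", quadratic_instrument=True
        )
        rows.append(
            {
                "seed": seed,
                "balance_rejections": int((non_height["p"] < 0.05).sum()),
                "balance_rows": len(non_height),
                "sargan_p": overid.sargan_result.pvalue,
            }
        )
    return pd.DataFrame(rows)
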