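"""Shared fixtures: simulated sessions and cohorts reused across modules.

Cohort-scale fixtures are session-scoped because simulation + metric
extraction dominates the suite's runtime; every test treats them as
read-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pdmotion.dimensionality import impute_median, standardize
from pdmotion.motor_metrics import METRIC_NAMES, extract_all, metrics_table
from pdmotion.simulator import SeverityProfile, SimConfig, simulate_cohort, simulate_subject


@pytest.fixture(scope="session")
def moderate_session():
    """One complete 14-task session at moderate severities."""
    profile = SeverityProfile(0.4, 0.5, 0.4, 0.5, 0.4)
    return simulate_subject(profile, SimConfig(), seed=21, subject_id="S_mod")


@pytest.fixture(scope="session")
def cohort50():
    """Continuous-severity cohort at study scale (n=50) with extracted
    metrics, UPDRS totals, and ground-truth severities."""
    cohort = simulate_cohort(SimConfig(n_subjects=50, seed=7))
    vectors = [extract_all(s) for s in cohort.sessions]
    table = metrics_table(vectors)
    X = impute_median(table[list(METRIC_NAMES)])
    return {
        "cohort": cohort,
        "table": table,
        "X": X.to_numpy(float),
        "X_df": X,
        "y": cohort.updrs["total"].to_numpy(float),
        "truth": cohort.truth,
    }


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Ten continuous-severity cohorts (n=50, seeds 0..9) for the
    score-prediction parameter-recovery suite."""
    out = []
    for seed in range(10):
        cohort = simulate_cohort(SimConfig(n_subjects=50, seed=seed))
        table = metrics_table([extract_all(s) for s in cohort.sessions])
        out.append(
            {
                "X": impute_median(table[list(METRIC_NAMES)]).to_numpy(float),
                "y": cohort.updrs["total"].to_numpy(float),
                "truth": cohort.truth,
            }
        )
    return out


@pytest.fixture(scope="session")
def phenotype_cohorts():
    """Ten planted-3-phenotype cohorts (n=50, seeds 0..9) for the
    clustering parameter-recovery suite."""
    out = []
    for seed in range(10):
        cohort = simulate_cohort(SimConfig(n_subjects=50, seed=seed, planted_k=3))
        table = metrics_table([extract_all(s) for s in cohort.sessions])
        Xs = standardize(impute_median(table[list(METRIC_NAMES)]))
        codes = pd.Categorical(cohort.truth["phenotype"]).codes
        out.append({"Xs": Xs.to_numpy(float), "truth": np.asarray(codes),
                    "updrs": cohort.updrs})
    return out
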