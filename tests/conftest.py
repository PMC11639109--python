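"""Shared fixtures: the reconstructed headline dataset and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from camimc import (
    study_default_config,
    score_records,
    simulate_cohort,
)

#: The completely-printed cut-off-3 confusion table of the study cohort:
#: 52 true positives, 2 false negatives, 32 false positives, 538 true
#: negatives over 624 paired observations.
HEADLINE_COUNTS = dict(tp=52, fn=2, fp=32, tn=538)


@pytest.fixture(scope="session")
def headline_scores():
    """Dichotomised observation-level data reconstructed from the printed
    counts: score 3 for test-positive rows, 0 for test-negative."""
    c = HEADLINE_COUNTS
    scores = np.r_[
        np.full(c["tp"], 3), np.full(c["fn"], 0),
        np.full(c["fp"], 3), np.full(c["tn"], 0),
    ]
    labels = np.r_[
        np.ones(c["tp"] + c["fn"], dtype=bool),
        np.zeros(c["fp"] + c["tn"], dtype=bool),
    ]
    return scores, labels


@pytest.fixture(scope="session")
def headline_frame(headline_scores):
    scores, labels = headline_scores
    return pd.DataFrame({"camimc_total": scores, "reference_delirium": labels})


@pytest.fixture(scope="session")
def default_config():
    return study_default_config()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Study-sized synthetic cohort (155 patients, 3 days)."""
    return simulate_cohort(default_config, seed=20240101)


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for parameter-recovery checks (10 000 patients)."""
    cfg = study_default_config().model_copy(update={"n_patients": 10_000})
    return simulate_cohort(cfg, seed=20240202)


@pytest.fixture(scope="session")
def large_scored(large_cohort):
    return score_records(large_cohort.assessments, large_cohort.baseline)
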