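"""Shared fixtures: toy table builders and session-scoped synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskpipe import cohort, features, pipeline, scoring
from riskpipe.synthetic import EPOCH, SimConfig, generate_cohort

# Parameter-recovery cohort: moderate planted log-ORs at generous base rates
# (strong effects would show visible non-collapsibility attenuation in the
# marginal 2x2 odds ratio; see docs/methods.md), 30% subpopulation so both
# isolation and within-subpopulation recovery are checkable.
RECOVERY_CONFIG = SimConfig(
    n_patients=50_000,
    subpop_fraction=0.3,
    baseline_prevalence=0.013,
    shared_effects=(1.5, 1.0, 0.6, -0.5),
    shared_base_rates=(0.10, 0.15, 0.25, 0.30),
    subpop_effects=(1.2, -0.4),
    subpop_base_rates=(0.15, 0.25),
    n_noise_codes=80,
    events_per_year=3.0,
    seed=5,
)

# One shared code at log-OR 2.0, base rate 0.05: the minimal planted-effect
# recovery scenario.
SINGLE_CODE_CONFIG = SimConfig(
    n_patients=50_000,
    baseline_prevalence=0.01,
    shared_effects=(2.0,),
    shared_base_rates=(0.05,),
    subpop_effects=(),
    subpop_base_rates=(),
    n_noise_codes=150,
    events_per_year=4.0,
    seed=0,
)

SMALL_CONFIG = SimConfig(
    n_patients=3_000,
    subpop_fraction=1.0,
    n_noise_codes=60,
    events_per_year=4.0,
    seed=11,
)


def make_events(*rows) -> pd.DataFrame:
    """Build an event table from (patient_id, day, code_type, code[, flag])."""
    recs = []
    for r in rows:
        pid, day, ctype, code = r[:4]
        flag = r[4] if len(r) > 4 else ""
        recs.append((pid, EPOCH + pd.Timedelta(days=day), ctype, code, flag))
    return pd.DataFrame(
        recs, columns=["patient_id", "date", "code_type", "code", "value_flag"]
    )


def make_demographics(patient_ids, birth_year=1960, sex="F") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "sex": sex,
            "birth_year": birth_year,
            "race": "White",
            "marital_status": "Married",
        }
    )


def fit_full_cohort(result, min_count: int = 5) -> scoring.RiskModel:
    """Fit PRS on a whole included cohort (no split): parameter recovery mode."""
    labels = pipeline.build_labels(result.events, result.demographics)
    censored = cohort.censor_case_records(result.events, labels)
    included = labels[labels["included"]]
    feats = features.extract_features(censored, result.demographics)
    feats = feats[feats["patient_id"].isin(set(included["patient_id"]))]
    vocab = features.vocabulary_from_features(feats, min_count=min_count)
    return scoring.fit_prs(feats, included, vocab)


def pairwise_auc(scores, is_case) -> float:
    """Brute-force AUC oracle: (wins + half-ties) over all case-control pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    cases, controls = s[y], s[~y]
    diff = cases[:, None] - controls[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


@pytest.fixture(scope="session")
def recovery_cohort():
    return generate_cohort(RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def recovery_model(recovery_cohort):
    return fit_full_cohort(recovery_cohort)


@pytest.fixture(scope="session")
def single_code_cohort():
    return generate_cohort(SINGLE_CODE_CONFIG)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    return pipeline.run_pipeline(
        small_cohort.events, small_cohort.demographics, split_seed=2
    )
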