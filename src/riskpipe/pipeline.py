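"""End-to-end single-cohort pipeline: label, censor, split, fit, validate.

Ties the stage modules together in the order a registry analysis runs
them: case finding and inclusion filtering, pre-event censoring, a random
half split, vocabulary and score fitting on the training arm, threshold
calibration on the training controls, and simulated-prospective scoring
of the held-out arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cohort, features, scoring, validation
from .synthetic import MARKER_CODE


def build_labels(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    case_def: cohort.CaseDefinition | None = None,
    marker_code: str = MARKER_CODE,
) -> pd.DataFrame:
    """Case finding, inclusion criteria, and case-specific exclusions."""
    labels = cohort.find_cases(events, case_def, marker_code=marker_code)
    labels = cohort.apply_inclusion(events, demographics, labels)
    return cohort.apply_case_exclusions(events, labels)


@dataclass
class FittedArm:
    """A trained scorer: vocabulary, PRS table, and calibrated cutoffs."""

    vocabulary: pd.DataFrame
    model: scoring.RiskModel
    thresholds: scoring.ThresholdSet
    n_train: int


def fit_training_arm(
    train_features: pd.DataFrame,
    train_labels: pd.DataFrame,
    specificity_targets=(0.90, 0.95),
    min_count: int = 5,
) -> FittedArm:
    """Vocabulary, PRS fit, and control-percentile thresholds for one arm."""
    vocab = features.vocabulary_from_features(train_features, min_count=min_count)
    model = scoring.fit_prs(train_features, train_labels, vocab)
    control_ids = train_labels.loc[~train_labels["is_case"], "patient_id"]
    control_ors = validation.overall_risk_scores(
        train_features[train_features["patient_id"].isin(control_ids)],
        model,
        all_patient_ids=pd.Index(control_ids),
    )
    thresholds = scoring.select_thresholds(control_ors, specificity_targets)
    return FittedArm(vocab, model, thresholds, n_train=len(train_labels))


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    fitted: FittedArm
    test_ors: pd.Series
    auc: float
    panel: pd.DataFrame
    lead: pd.DataFrame
    test_trajectories: pd.DataFrame


def run_pipeline(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    split_seed: int = 0,
    specificity_targets=(0.90, 0.95),
    min_count: int = 5,
    case_def: cohort.CaseDefinition | None = None,
    marker_code: str = MARKER_CODE,
    stratify_split: bool = False,
) -> PipelineResult:
    """Full train/validate cycle on one cohort's event and demographics tables."""
    labels = build_labels(events, demographics, case_def, marker_code=marker_code)
    censored = cohort.censor_case_records(events, labels)
    labels = cohort.split_train_test(labels, split_seed, stratify=stratify_split)

    feats = features.extract_features(censored, demographics)
    train_ids = labels.loc[labels["arm"] == "train", "patient_id"]
    test_ids = labels.loc[labels["arm"] == "test", "patient_id"]
    train_feats = feats[feats["patient_id"].isin(set(train_ids))]
    test_feats = feats[feats["patient_id"].isin(set(test_ids))]

    fitted = fit_training_arm(
        train_feats,
        labels[labels["patient_id"].isin(set(train_ids))],
        specificity_targets,
        min_count,
    )
    test_ors = validation.overall_risk_scores(
        test_feats, fitted.model, all_patient_ids=pd.Index(test_ids)
    )
    test_labels = labels[labels["patient_id"].isin(set(test_ids))]
    auc = validation.roc_auc(
        test_ors.to_numpy(),
        test_ors.index.to_series().map(
            test_labels.set_index("patient_id")["is_case"]
        ).to_numpy(bool),
    )
    panel = validation.metric_panel(test_ors, test_labels, fitted.thresholds)
    traj = validation.trajectory_table(test_feats, fitted.model)
    lead = validation.lead_times(traj, test_labels, fitted.thresholds)
    return PipelineResult(labels, fitted, test_ors, auc, panel, lead, traj)
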