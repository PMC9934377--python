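"""Headline comparisons: subpopulation-trained vs general-trained scorers.

The three-arm design trains the same scoring model on (A) the
subpopulation's training half, (B) a uniform random general-cohort sample
of exactly the same size, and (C) the full general cohort minus the
subpopulation validation patients, and evaluates all three on the
identical subpopulation validation half.  When the subpopulation carries
codes whose effects exist only inside it, arm B sees that signal only
diluted by the subpopulation's share of the general cohort, so arm A's
tailored model is expected to rank validation patients better.

Also provides the dual-cohort odds-ratio table: per-feature ORs computed
separately in the subpopulation and the general cohort, each Z-scaled
within its cohort so the two rankings are comparable despite the cohorts'
very different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import cohort, features, scoring, validation
from .pipeline import FittedArm, build_labels, fit_training_arm
from .synthetic import SimConfig, generate_cohort


@dataclass(frozen=True)
class ExperimentConfig:
    """Three-arm comparison settings over one synthetic general cohort."""

    sim: SimConfig
    split_seed: int = 0
    specificity_targets: tuple[float, ...] = (0.90, 0.95)
    min_count: int = 5
    arm_b_exclude_all_subpop: bool = False


@dataclass
class ArmResult:
    name: str
    n_train: int
    auc: float
    panel: pd.DataFrame
    fitted: FittedArm


@dataclass
class ComparisonResult:
    arms: dict[str, ArmResult]
    validation_ids: frozenset[str]
    labels: pd.DataFrame

    @property
    def aucs(self) -> dict[str, float]:
        return {name: arm.auc for name, arm in self.arms.items()}


def _evaluate_arm(
    name: str,
    train_ids: pd.Index,
    val_ids: pd.Index,
    feats: pd.DataFrame,
    labels: pd.DataFrame,
    cfg: ExperimentConfig,
) -> ArmResult:
    by_pid = labels.set_index("patient_id")
    train_feats = feats[feats["patient_id"].isin(set(train_ids))]
    fitted = fit_training_arm(
        train_feats,
        labels[labels["patient_id"].isin(set(train_ids))],
        cfg.specificity_targets,
        cfg.min_count,
    )
    val_feats = feats[feats["patient_id"].isin(set(val_ids))]
    ors = validation.overall_risk_scores(
        val_feats, fitted.model, all_patient_ids=pd.Index(val_ids)
    )
    y = ors.index.to_series().map(by_pid["is_case"]).to_numpy(bool)
    auc = validation.roc_auc(ors.to_numpy(), y)
    panel = validation.metric_panel(
        ors, labels[labels["patient_id"].isin(set(val_ids))], fitted.thresholds
    )
    return ArmResult(name, n_train=len(train_ids), auc=auc, panel=panel, fitted=fitted)


def run_three_arm_comparison(cfg: ExperimentConfig) -> ComparisonResult:
    """Train subpop / size-matched general / full general; validate on subpop.

    The general cohort is generated from ``cfg.sim`` (which must have
    ``subpop_fraction`` strictly below 1 so a strict superpopulation
    exists).  All randomness derives from the simulation seed and
    ``split_seed``, making the whole experiment reproducible.
    """
    if not 0 < cfg.sim.subpop_fraction < 1:
        raise ValueError(
            "three-arm comparison needs a general cohort strictly containing "
            "the subpopulation (0 < subpop_fraction < 1)"
        )
    sim = generate_cohort(cfg.sim)
    labels = build_labels(sim.events, sim.demographics)
    censored = cohort.censor_case_records(sim.events, labels)
    feats = features.extract_features(censored, sim.demographics)

    included = labels[labels["included"]]
    subpop_ids = included.loc[
        included["first_marker_date"].notna(), "patient_id"
    ].to_numpy()
    rng = np.random.default_rng(cfg.split_seed)
    perm = rng.permutation(np.sort(subpop_ids))
    half = len(perm) // 2
    val_ids = pd.Index(np.sort(perm[:half]))
    arm_a_ids = pd.Index(np.sort(perm[half:]))

    general_ids = pd.Index(included["patient_id"]).difference(val_ids)
    pool_b = general_ids
    if cfg.arm_b_exclude_all_subpop:
        pool_b = pool_b.difference(pd.Index(subpop_ids))
    if len(pool_b) < len(arm_a_ids):
        raise ValueError(
            f"general pool ({len(pool_b)}) smaller than requested size-matched "
            f"sample ({len(arm_a_ids)})"
        )
    arm_b_ids = pd.Index(
        np.sort(rng.choice(pool_b.to_numpy(), size=len(arm_a_ids), replace=False))
    )

    arms = {
        "subpop": _evaluate_arm("subpop", arm_a_ids, val_ids, feats, labels, cfg),
        "general_matched": _evaluate_arm(
            "general_matched", arm_b_ids, val_ids, feats, labels, cfg
        ),
        "general_all": _evaluate_arm(
            "general_all", general_ids, val_ids, feats, labels, cfg
        ),
    }
    assert arms["general_matched"].n_train == arms["subpop"].n_train
    return ComparisonResult(arms, frozenset(val_ids), labels)


def run_three_arm_over_seeds(
    base_sim: SimConfig, seeds, **cfg_kwargs
) -> pd.DataFrame:
    """Repeat the three-arm comparison across simulation seeds.

    Returns one row per seed with the three validation AUCs; the split
    seed is tied to the simulation seed so each replicate is independent
    and fully determined by its seed.
    """
    rows = []
    for seed in seeds:
        sim_cfg = SimConfig(**{**base_sim.__dict__, "seed": int(seed)})
        res = run_three_arm_comparison(
            ExperimentConfig(sim=sim_cfg, split_seed=int(seed), **cfg_kwargs)
        )
        rows.append({"seed": int(seed), **res.aucs})
    return pd.DataFrame(rows)


def _cohort_or_frame(
    feats: pd.DataFrame, labels: pd.DataFrame, keys: pd.Index, suffix: str
) -> pd.DataFrame:
    lab = labels.set_index("patient_id")["is_case"]
    n_cases = int(lab.sum())
    n_controls = int((~lab).sum())
    present = feats.drop_duplicates(["patient_id", "key"]).copy()
    present["is_case"] = present["patient_id"].map(lab)
    present = present[present["is_case"].notna()]
    by_key = present.groupby("key")["is_case"]
    a = by_key.sum().reindex(keys, fill_value=0).astype(float)
    w = by_key.size().reindex(keys, fill_value=0).astype(float)
    c = w - a
    b = n_cases - a
    d = n_controls - c
    smoothed = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a2, b2, c2, d2 = (x + 0.5 * smoothed for x in (a, b, c, d))
    out = pd.DataFrame(
        {
            f"cases_with_{suffix}": a.astype(int),
            f"controls_with_{suffix}": c.astype(int),
            f"or_{suffix}": (a2 / b2) / (c2 / d2),
            f"smoothed_{suffix}": smoothed,
        }
    )
    out[f"z_{suffix}"] = scoring.z_scale_ors(out[f"or_{suffix}"])
    return out


def dual_cohort_or_table(
    subpop_features: pd.DataFrame,
    subpop_labels: pd.DataFrame,
    general_features: pd.DataFrame,
    general_labels: pd.DataFrame,
    keys=None,
    with_p_values: bool = False,
) -> pd.DataFrame:
    """Per-feature OR and within-cohort Z-scaled OR in both cohorts.

    ``keys`` fixes the displayed feature set (default: features present in
    both cohorts); Z-scaling is computed over exactly that set within each
    cohort.  With ``with_p_values`` a chi-square two-proportion test
    compares the feature's case rate between cohorts.
    """
    if keys is None:
        keys = pd.Index(
            sorted(set(subpop_features["key"]) & set(general_features["key"]))
        )
    else:
        keys = pd.Index(keys)
    sub = _cohort_or_frame(subpop_features, subpop_labels, keys, "subpop")
    gen = _cohort_or_frame(general_features, general_labels, keys, "general")
    out = pd.concat([sub, gen], axis=1)
    out.index.name = "key"
    if with_p_values:
        n_cases_s = int(subpop_labels["is_case"].sum())
        n_cases_g = int(general_labels["is_case"].sum())
        pvals = []
        for key, row in out.iterrows():
            table = np.array(
                [
                    [row["cases_with_subpop"], n_cases_s - row["cases_with_subpop"]],
                    [row["cases_with_general"], n_cases_g - row["cases_with_general"]],
                ]
            )
            if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                pvals.append(float("nan"))
            else:
                pvals.append(float(chi2_contingency(table)[1]))
        out["p_diff"] = pvals
    return out.reset_index()
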