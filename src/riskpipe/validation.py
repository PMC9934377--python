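"""Simulated-prospective validation: trajectories, metric panels, ROC, lead time.

Each test patient's record is replayed in chronological order.  The
cumulative risk at time t,

    Risk_t = PRS_i + PRS_j + ... + PRS_z,

sums the scores of all distinct variables first observed on or before t
(same-day variables are aggregated before the day's value is emitted, so
the trajectory is invariant to within-day event ordering).  The overall
risk score ORS = max_t Risk_t is the quantity compared against the
calibrated cutoffs; a patient is flagged positive iff ORS strictly
exceeds the cutoff, and for detected cases the lead time is the interval
from the first threshold crossing to the first case-defining event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import RiskModel, ThresholdSet

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class RiskTrajectory:
    """One patient's chronological cumulative-score curve.

    ``dates``/``risk`` are aligned arrays with strictly increasing dates;
    ``ors`` is the running maximum's final value (0.0 by convention for an
    empty record, flagged via ``empty``).
    """

    patient_id: str
    dates: np.ndarray
    risk: np.ndarray
    ors: float

    @property
    def empty(self) -> bool:
        return self.dates.size == 0

    def first_crossing(self, cutoff: float) -> pd.Timestamp | None:
        """Earliest date with Risk_t strictly above the cutoff, if any."""
        above = np.flatnonzero(self.risk > cutoff)
        if above.size == 0:
            return None
        return pd.Timestamp(self.dates[above[0]])


def trajectory_table(features: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Long (patient_id, date, risk) cumulative-score table for all patients.

    Each distinct variable contributes its PRS once, at first occurrence;
    out-of-vocabulary variables contribute 0 but keep their date in the log.
    """
    if features.empty:
        return pd.DataFrame(columns=["patient_id", "date", "risk"])
    f = features.rename(columns={"first_date": "date"})[
        ["patient_id", "key", "date"]
    ].copy()
    f["prs"] = f["key"].map(model.prs).fillna(0.0)
    daily = (
        f.groupby(["patient_id", "date"], sort=True)["prs"].sum().reset_index()
    )
    daily["risk"] = daily.groupby("patient_id")["prs"].cumsum()
    return daily[["patient_id", "date", "risk"]]


def build_trajectory(
    patient_features: pd.DataFrame, model: RiskModel, patient_id: str | None = None
) -> RiskTrajectory:
    """Trajectory for a single patient's extracted feature frame."""
    if patient_id is None:
        ids = patient_features["patient_id"].unique()
        if len(ids) > 1:
            raise ValueError("feature frame spans multiple patients; pass patient_id")
        patient_id = ids[0] if len(ids) else ""
    sub = patient_features[patient_features["patient_id"] == patient_id]
    tab = trajectory_table(sub, model)
    if tab.empty:
        return RiskTrajectory(patient_id, np.array([], "datetime64[ns]"),
                              np.array([]), 0.0)
    return RiskTrajectory(
        patient_id,
        tab["date"].to_numpy(),
        tab["risk"].to_numpy(),
        float(tab["risk"].max()),
    )


def overall_risk_scores(
    features: pd.DataFrame,
    model: RiskModel,
    all_patient_ids: pd.Index | None = None,
) -> pd.Series:
    """ORS per patient (max of the cumulative trajectory; 0 for empty records)."""
    tab = trajectory_table(features, model)
    ors = tab.groupby("patient_id")["risk"].max() if not tab.empty else pd.Series(
        dtype=float
    )
    if all_patient_ids is not None:
        ors = ors.reindex(all_patient_ids, fill_value=0.0)
    ors.name = "ors"
    return ors


def classify(ors: float | pd.Series, thresholds: ThresholdSet) -> dict | pd.DataFrame:
    """Per-threshold positivity: positive iff ORS strictly exceeds the cutoff."""
    if isinstance(ors, pd.Series):
        return pd.DataFrame({t: ors > c for t, c in thresholds.items()})
    return {t: bool(ors > c) for t, c in thresholds.items()}


def _pct(x: float) -> int:
    return int(round(100.0 * x))


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Derived metrics from a confusion matrix, exact and integer-percent.

    The rounded variants (``*_pct``, ``lr_*_rounded``) recompute the
    likelihood ratios from the integer-percent sensitivity/specificity —
    the arithmetic conventionally shown in printed summary tables.
    """
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    sens_pct, spec_pct = _pct(sens), _pct(spec)
    lr_pos_r = round(sens_pct / (100 - spec_pct), 2) if spec_pct < 100 else float("inf")
    lr_neg_r = round((100 - sens_pct) / spec_pct, 2) if spec_pct > 0 else float("inf")
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
        "lr_pos": lr_pos, "lr_neg": lr_neg,
        "sens_pct": sens_pct, "spec_pct": spec_pct,
        "ppv_pct": _pct(ppv) if tp + fp else None,
        "npv_pct": _pct(npv) if tn + fn else None,
        "lr_pos_rounded": lr_pos_r, "lr_neg_rounded": lr_neg_r,
    }


def metric_panel(
    ors: pd.Series, labels: pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """One metric row per calibrated threshold over the scored patients."""
    lab = labels.set_index("patient_id")["is_case"].reindex(ors.index)
    if lab.isna().any():
        raise ValueError("labels missing for some scored patients")
    y = lab.to_numpy(bool)
    s = ors.to_numpy(float)
    rows = []
    for target, cutoff in thresholds.items():
        pos = s > cutoff
        row = metrics_from_counts(
            tp=int((pos & y).sum()), tn=int((~pos & ~y).sum()),
            fp=int((pos & ~y).sum()), fn=int((~pos & y).sum()),
        )
        rows.append({"spec_target": target, "cutoff": cutoff, **row})
    return pd.DataFrame(rows)


def roc_auc(scores, is_case) -> float:
    """Area under the ROC curve in its rank (Mann-Whitney) form.

    AUC = P(score_case > score_control) + 0.5 P(tie) over all
    case-control pairs; midranks make this exact under ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs at least one case and one control")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, is_case) -> pd.DataFrame:
    """Empirical ROC curve as (fpr, tpr, threshold) rows, threshold-descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)) , s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    return pd.DataFrame(
        {
            "fpr": np.r_[0, fps] / max(int((~y).sum()), 1),
            "tpr": np.r_[0, tps] / max(int(y.sum()), 1),
            "threshold": np.r_[np.inf, s[distinct]],
        }
    )


def lead_times(
    trajectories: pd.DataFrame,
    labels: pd.DataFrame,
    thresholds: ThresholdSet,
) -> pd.DataFrame:
    """Mean lead time (years) from first crossing to event, per threshold.

    Only detected cases (ORS above the cutoff) contribute; the 95% CI uses
    the normal approximation.  Crossings use only pre-event data because
    case records are censored upstream, so leads are strictly positive.
    """
    case_events = labels.loc[labels["is_case"]].set_index("patient_id")[
        "first_event_date"
    ]
    traj = trajectories[trajectories["patient_id"].isin(case_events.index)]
    rows = []
    for target, cutoff in thresholds.items():
        crossed = traj[traj["risk"] > cutoff]
        first_cross = crossed.groupby("patient_id")["date"].min()
        event = first_cross.index.to_series(index=first_cross.index).map(case_events)
        lead = (event - first_cross).dt.days.to_numpy() / DAYS_PER_YEAR
        k = lead.size
        mean = float(lead.mean()) if k else float("nan")
        se = float(lead.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
        rows.append(
            {
                "spec_target": target,
                "cutoff": cutoff,
                "n_detected": int(k),
                "mean_lead_years": mean,
                "ci_low": mean - 1.96 * se if k > 1 else float("nan"),
                "ci_high": mean + 1.96 * se if k > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
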