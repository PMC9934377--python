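"""Cohort construction: case definition, inclusion/exclusion, censoring, split.

The case definition is a set of ICD-9-style diagnosis-code prefixes
(default E95*, 965*, 967*, 969*, 881*, covering suicide and self-inflicted
injury, poisonings, and open wounds of the forearm/wrist), optionally
supplemented by an external case list emulating death-certificate linkage.
Codes are normalized by stripping dots before prefix matching, so
``E950.0`` and ``E9500`` behave identically.

Inclusion requires three or more visits (distinct patient-dates with at
least one event), a span of at least 30 days between first and last visit,
and at least one event at an age between 10 and 90 years.  Cases are
additionally excluded when they have no documentation strictly before the
first case-defining event, or when that event precedes the first
subpopulation-marker diagnosis; same-day marker/event ties are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import MARKER_CODE

DEFAULT_CASE_PREFIXES = ("E95", "965", "967", "969", "881")

EXCLUSION_REASONS = (
    "none", "no_prior_data", "event_before_marker",
    "too_few_visits", "span_too_short", "age_out_of_range",
)

LABEL_COLUMNS = [
    "patient_id", "is_case", "first_event_date", "first_marker_date",
    "included", "exclusion_reason",
]


def normalize_code(code: str) -> str:
    """Dialect normalization: strip dots and whitespace, uppercase."""
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class CaseDefinition:
    """Diagnosis-code prefixes plus an optional external case-date map."""

    code_prefixes: tuple[str, ...] = DEFAULT_CASE_PREFIXES
    external_cases: Mapping[str, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        if not self.code_prefixes or any(not str(p).strip() for p in self.code_prefixes):
            raise ValueError("code_prefixes must be non-empty strings")

    @property
    def normalized_prefixes(self) -> tuple[str, ...]:
        return tuple(normalize_code(p) for p in self.code_prefixes)


def _empty_labels() -> pd.DataFrame:
    labels = pd.DataFrame(columns=LABEL_COLUMNS)
    labels["is_case"] = labels["is_case"].astype(bool)
    labels["included"] = labels["included"].astype(bool)
    return labels


def find_cases(
    events: pd.DataFrame,
    case_def: CaseDefinition | None = None,
    marker_code: str = MARKER_CODE,
) -> pd.DataFrame:
    """Label each patient as case/control and date first event and marker.

    A patient is a case iff any DX code matches a case prefix (after dot
    stripping) or the patient appears in the external case list; the first
    event date is the earliest qualifying date, with the external date
    participating in the minimum.  The first marker date is the earliest
    DX event whose normalized code starts with ``marker_code``.
    """
    case_def = case_def or CaseDefinition()
    pids = pd.Index(events["patient_id"].unique())
    if case_def.external_cases:
        pids = pids.union(pd.Index(case_def.external_cases.keys()))
    pids = pids.sort_values()

    dx = events[events["code_type"] == "DX"]
    norm = dx["code"].map(normalize_code)

    hit = norm.str.startswith(case_def.normalized_prefixes)
    first_event = dx.loc[hit].groupby("patient_id")["date"].min()
    if case_def.external_cases:
        ext = pd.Series(
            {str(k): pd.Timestamp(v) for k, v in case_def.external_cases.items()}
        )
        first_event = (
            pd.concat([first_event, ext]).groupby(level=0).min()
        )

    marker_hit = norm.str.startswith(normalize_code(marker_code))
    first_marker = dx.loc[marker_hit].groupby("patient_id")["date"].min()

    labels = pd.DataFrame({"patient_id": pids})
    labels["is_case"] = labels["patient_id"].isin(first_event.index)
    labels["first_event_date"] = labels["patient_id"].map(first_event)
    labels["first_marker_date"] = labels["patient_id"].map(first_marker)
    labels["included"] = True
    labels["exclusion_reason"] = "none"
    return labels


def apply_inclusion(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Apply the three inclusion criteria; failures set an exclusion reason.

    Criteria: >=3 visits (distinct event dates), >=30 days between first
    and last visit (inclusive boundary), and at least one event at an age
    between 10 and 90 (event year minus birth year; missing birth year
    fails closed).  Patients in demographics but absent from the event
    table count as zero visits.  When multiple criteria fail, the recorded
    reason follows the order visits, span, age.
    """
    labels = labels.copy()
    universe = labels["patient_id"]
    if not demographics.empty:
        extra = pd.Index(demographics["patient_id"].astype(str)).difference(universe)
        if len(extra):
            add = pd.DataFrame({"patient_id": extra.sort_values()})
            add["is_case"] = False
            add["first_event_date"] = pd.NaT
            add["first_marker_date"] = pd.NaT
            add["included"] = True
            add["exclusion_reason"] = "none"
            labels = pd.concat([labels, add], ignore_index=True)
            labels = labels.sort_values("patient_id", kind="mergesort").reset_index(
                drop=True
            )

    grp = events.groupby("patient_id")["date"]
    n_visits = grp.nunique()
    span_days = (grp.max() - grp.min()).dt.days

    birth = demographics.set_index("patient_id")["birth_year"] if not \
        demographics.empty else pd.Series(dtype=float)
    ev = events[["patient_id", "date"]].copy()
    ev["age"] = ev["date"].dt.year - ev["patient_id"].map(birth)
    age_ok = ev.assign(ok=ev["age"].between(10, 90)).groupby("patient_id")["ok"].any()

    pid = labels["patient_id"]
    visits = pid.map(n_visits).fillna(0)
    span = pid.map(span_days).fillna(-1)
    age = pid.map(age_ok).eq(True)

    reason = np.where(
        visits < 3, "too_few_visits",
        np.where(span < 30, "span_too_short", np.where(~age, "age_out_of_range", "none")),
    )
    labels["included"] = reason == "none"
    labels["exclusion_reason"] = reason
    return labels


def apply_case_exclusions(events: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Exclude cases with no pre-event documentation or an event that
    precedes the first marker diagnosis.

    Applies only to cases still included; same-day marker/event ties are
    retained, and cases with no marker at all (general-cohort patients)
    are not subject to the temporal-ordering rule.
    """
    labels = labels.copy()
    case_rows = labels["is_case"] & labels["included"]

    ev = events.merge(
        labels.loc[case_rows, ["patient_id", "first_event_date"]],
        on="patient_id", how="inner",
    )
    has_prior = (
        (ev["date"] < ev["first_event_date"]).groupby(ev["patient_id"]).any()
    )
    prior = labels["patient_id"].map(has_prior).eq(True)

    no_prior = case_rows & ~prior
    labels.loc[no_prior, "included"] = False
    labels.loc[no_prior, "exclusion_reason"] = "no_prior_data"

    reversed_order = (
        labels["is_case"] & labels["included"]
        & labels["first_marker_date"].notna()
        & (labels["first_event_date"] < labels["first_marker_date"])
    )
    labels.loc[reversed_order, "included"] = False
    labels.loc[reversed_order, "exclusion_reason"] = "event_before_marker"
    return labels


def censor_case_records(events: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Drop every case event on or after the first case-defining event.

    Controls pass through untouched; the operation is idempotent.
    """
    cutoff = events["patient_id"].map(
        labels.loc[labels["is_case"]].set_index("patient_id")["first_event_date"]
    )
    keep = cutoff.isna() | (events["date"] < cutoff)
    return events.loc[keep].reset_index(drop=True)


def classify_temporal_order(labels: pd.DataFrame) -> dict[str, int]:
    """Count marker-first / event-first / same-day cases (pre-exclusion)."""
    cases = labels[
        labels["is_case"]
        & labels["first_event_date"].notna()
        & labels["first_marker_date"].notna()
    ]
    marker_first = int((cases["first_marker_date"] < cases["first_event_date"]).sum())
    event_first = int((cases["first_event_date"] < cases["first_marker_date"]).sum())
    same_day = int((cases["first_event_date"] == cases["first_marker_date"]).sum())
    return {"marker_first": marker_first, "event_first": event_first,
            "same_day": same_day}


def split_train_test(
    labels: pd.DataFrame, split_seed: int, stratify: bool = False
) -> pd.DataFrame:
    """Randomly halve the included patients into train/test arms.

    Arm sizes differ by at most one; excluded patients get no arm.  With
    ``stratify`` the split is done separately within cases and controls.
    """
    included = labels.loc[labels["included"]]
    if len(included) < 2:
        raise ValueError("need at least 2 included patients to split")
    rng = np.random.default_rng(split_seed)
    labels = labels.copy()
    labels["arm"] = pd.NA

    def assign(ids: np.ndarray) -> pd.Series:
        perm = rng.permutation(np.sort(ids))
        n_train = math.ceil(len(perm) / 2)
        return pd.Series(
            np.where(np.arange(len(perm)) < n_train, "train", "test"), index=perm
        )

    if stratify:
        parts = [
            assign(included.loc[included["is_case"] == flag, "patient_id"].to_numpy())
            for flag in (True, False)
            if (included["is_case"] == flag).any()
        ]
        arm = pd.concat(parts)
    else:
        arm = assign(included["patient_id"].to_numpy())
    labels.loc[labels["included"], "arm"] = labels.loc[
        labels["included"], "patient_id"
    ].map(arm)
    return labels


@dataclass
class DemographicsSummary:
    """Per-category counts/percentages and the women:men ratio per group."""

    table: pd.DataFrame
    sex_ratio: dict[str, float] = field(default_factory=dict)


def summarize_demographics(
    labels: pd.DataFrame, demographics: pd.DataFrame
) -> DemographicsSummary:
    """Tabulate sex, race, and marital status for all / cases / controls."""
    if demographics.empty or labels.empty:
        return DemographicsSummary(
            pd.DataFrame(columns=["feature", "category", "n_all", "pct_all",
                                  "n_cases", "pct_cases", "n_controls",
                                  "pct_controls"]),
            {},
        )
    merged = demographics.merge(
        labels[["patient_id", "is_case"]], on="patient_id", how="inner"
    )
    groups = {
        "all": merged,
        "cases": merged[merged["is_case"]],
        "controls": merged[~merged["is_case"]],
    }
    rows = []
    for feat in ("sex", "race", "marital_status"):
        cats = sorted(merged[feat].dropna().unique())
        for cat in cats:
            row: dict[str, object] = {"feature": feat, "category": cat}
            for gname, g in groups.items():
                n = int((g[feat] == cat).sum())
                row[f"n_{gname}"] = n
                row[f"pct_{gname}"] = 100.0 * n / len(g) if len(g) else float("nan")
            rows.append(row)
    table = pd.DataFrame(rows)

    def ratio(g: pd.DataFrame) -> float:
        women = int((g["sex"] == "F").sum())
        men = int((g["sex"] == "M").sum())
        if men == 0:
            return float("inf") if women else float("nan")
        return women / men

    return DemographicsSummary(table, {k: ratio(g) for k, g in groups.items()})


def sex_ratio(n_women: int, n_men: int) -> float:
    """Women:men ratio with an infinity sentinel for a one-sex cohort."""
    if n_men == 0:
        return float("inf") if n_women else float("nan")
    return n_women / n_men


def exclusion_accounting(labels: pd.DataFrame) -> dict[str, int]:
    """Case bookkeeping: identified = included + per-reason exclusions."""
    cases = labels[labels["is_case"]]
    out = {"cases_identified": int(len(cases)),
           "cases_included": int(cases["included"].sum())}
    for reason in EXCLUSION_REASONS[1:]:
        out[reason] = int((cases["exclusion_reason"] == reason).sum())
    return out
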