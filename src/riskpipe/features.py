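"""Binary ever-coded feature representation with first-occurrence dates.

A feature key is the string ``code_type|code|value_flag`` for coded events
(the flag is empty except for lab results, which yield up to three keys:
low/normal/high) and ``DEMO|field|category`` for demographics.  Features
are binary at the patient level — a variable counts once no matter how
often it recurs — and each carries the date it first appears, which is
what the prospective cumulative-score replay consumes.  Demographic
features are treated as known from the patient's first visit onward, and
age enters as a per-decade category evaluated at the first visit.

The vocabulary is learned from the training arm only; scoring ignores
out-of-vocabulary features, but extraction retains them (flagged) so that
trajectory logs stay complete.
"""

from __future__ import annotations

import pandas as pd

DEMO_TYPE = "DEMO"
KEY_SEP = "|"


def feature_key(code_type: str, code: str, value_flag: str = "") -> str:
    return f"{code_type}{KEY_SEP}{code}{KEY_SEP}{value_flag}"


def split_key(key: str) -> tuple[str, str, str]:
    code_type, code, flag = key.split(KEY_SEP, 2)
    return code_type, code, flag


def _event_features(events: pd.DataFrame) -> pd.DataFrame:
    """Long (patient_id, key, first_date) from coded events."""
    if events.empty:
        return pd.DataFrame(columns=["patient_id", "key", "first_date"])
    ev = events.copy()
    flag = ev["value_flag"].fillna("").astype(str)
    ev["key"] = (
        ev["code_type"].astype(str) + KEY_SEP + ev["code"].astype(str) + KEY_SEP + flag
    )
    out = (
        ev.groupby(["patient_id", "key"], sort=True)["date"]
        .min()
        .rename("first_date")
        .reset_index()
    )
    return out


def _demo_features(
    events: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Demographic category features dated at the patient's first visit."""
    if demographics.empty or events.empty:
        return pd.DataFrame(columns=["patient_id", "key", "first_date"])
    first_visit = events.groupby("patient_id")["date"].min()
    demo = demographics[demographics["patient_id"].isin(first_visit.index)].copy()
    if demo.empty:
        return pd.DataFrame(columns=["patient_id", "key", "first_date"])
    demo["first_date"] = demo["patient_id"].map(first_visit)

    frames = []
    for field in ("sex", "race", "marital_status"):
        sub = demo[demo[field].notna()]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": sub["patient_id"],
                    "key": DEMO_TYPE + KEY_SEP + field + KEY_SEP + sub[field].astype(str),
                    "first_date": sub["first_date"],
                }
            )
        )
    aged = demo[demo["birth_year"].notna()]
    if not aged.empty:
        decade = (
            (aged["first_date"].dt.year - aged["birth_year"].astype(int)) // 10 * 10
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": aged["patient_id"],
                    "key": DEMO_TYPE + KEY_SEP + "age_decade" + KEY_SEP
                    + decade.astype(int).astype(str),
                    "first_date": aged["first_date"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def extract_features(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    vocabulary: pd.DataFrame | None = None,
    as_of_date: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Per-patient feature sets with first-occurrence dates.

    Returns a long frame ``patient_id, key, first_date`` (plus ``in_vocab``
    when a vocabulary is given) containing every feature whose first
    occurrence is on or before ``as_of_date`` (no cutoff: the whole
    record).  Case events must be censored upstream.
    """
    parts = [_event_features(events), _demo_features(events, demographics)]
    nonempty = [p for p in parts if not p.empty]
    feats = pd.concat(nonempty, ignore_index=True) if nonempty else parts[0]
    if as_of_date is not None:
        feats = feats[feats["first_date"] <= pd.Timestamp(as_of_date)]
    feats = feats.sort_values(["patient_id", "key"], kind="mergesort").reset_index(
        drop=True
    )
    if vocabulary is not None:
        feats["in_vocab"] = feats["key"].isin(vocabulary["key"])
    return feats


def vocabulary_from_features(
    features: pd.DataFrame, min_count: int = 5
) -> pd.DataFrame:
    """Vocabulary table from an extracted (training-arm) feature frame."""
    counts = (
        features.groupby("key", sort=True)["patient_id"].nunique()
        .rename("n_train_patients").reset_index()
    )
    counts = counts[counts["n_train_patients"] >= min_count].reset_index(drop=True)
    parts = counts["key"].str.split(KEY_SEP, n=2, expand=True)
    if counts.empty:
        parts = pd.DataFrame(columns=[0, 1, 2])
    counts["code_type"] = parts[0]
    counts["code"] = parts[1]
    counts["value_flag"] = parts[2]
    return counts[["key", "code_type", "code", "value_flag", "n_train_patients"]]


def build_vocabulary(
    train_events: pd.DataFrame,
    train_demographics: pd.DataFrame,
    min_count: int = 5,
) -> pd.DataFrame:
    """Learn the ordered feature vocabulary from the training arm.

    One key per distinct observed variable; features seen in fewer than
    ``min_count`` distinct training patients are dropped.  Raises on an
    empty training arm.
    """
    if train_events.empty and train_demographics.empty:
        raise ValueError("cannot build a vocabulary from an empty training arm")
    feats = extract_features(train_events, train_demographics)
    if feats.empty:
        raise ValueError("training arm has no extractable features")
    return vocabulary_from_features(feats, min_count=min_count)
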