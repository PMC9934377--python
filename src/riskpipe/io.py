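"""Reading and writing the pipeline's plain-text table formats.

All tables are CSV/TSV with a header row.  The event-table dialect is
``patient_id,date,code_type,code,value_flag`` with ISO-8601 dates,
``code_type`` one of DX/RX/LAB, and ``value_flag`` empty except for LAB
events where it is one of L/N/H.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import DEMO_COLUMNS, EVENT_COLUMNS

VALID_CODE_TYPES = frozenset({"DX", "RX", "LAB"})
VALID_LAB_FLAGS = frozenset({"L", "N", "H"})


class EventTableError(ValueError):
    """A malformed event-table file; the message names the line and column."""


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"line 1, column {missing[0]}: missing required column")
    df = df[EVENT_COLUMNS]

    def _first_bad(mask: pd.Series) -> int:
        # +2: one for the header line, one for 0- vs 1-based indexing
        return int(mask.idxmax()) + 2

    bad_type = ~df["code_type"].isin(VALID_CODE_TYPES)
    if bad_type.any():
        line = _first_bad(bad_type)
        raise EventTableError(
            f"line {line}, column code_type: unknown token "
            f"{df['code_type'].iloc[line - 2]!r}"
        )
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        line = _first_bad(dates.isna())
        raise EventTableError(
            f"line {line}, column date: unparseable date {df['date'].iloc[line - 2]!r}"
        )
    is_lab = df["code_type"] == "LAB"
    bad_flag = (is_lab & ~df["value_flag"].isin(VALID_LAB_FLAGS)) | (
        ~is_lab & (df["value_flag"] != "")
    )
    if bad_flag.any():
        line = _first_bad(bad_flag)
        raise EventTableError(
            f"line {line}, column value_flag: invalid flag "
            f"{df['value_flag'].iloc[line - 2]!r} for code_type "
            f"{df['code_type'].iloc[line - 2]!r}"
        )
    df["date"] = dates
    return df


def write_demographics(demographics: pd.DataFrame, path: str | Path) -> None:
    demographics.to_csv(path, index=False, columns=DEMO_COLUMNS)


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "patient_id", "is_case", "first_event_date", "first_marker_date",
        "included", "exclusion_reason",
    ]
    out = labels.copy()
    if "arm" in out.columns:
        cols = cols + ["arm"]
    out.to_csv(path, index=False, columns=cols)


def write_vocabulary(vocabulary: pd.DataFrame, path: str | Path) -> None:
    vocabulary.to_csv(
        path, sep="\t", index=False,
        columns=["code_type", "code", "value_flag", "n_train_patients"],
    )


def write_risk_model(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_metric_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Metric panel TSV in the conventional column order."""
    cols = [
        "spec_target", "cutoff", "spec_pct", "sens_pct", "ppv_pct", "npv_pct",
        "tp", "tn", "fp", "fn", "lr_pos_rounded", "lr_neg_rounded",
        "sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg",
    ]
    panel.to_csv(path, sep="\t", index=False,
                 columns=[c for c in cols if c in panel.columns])
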