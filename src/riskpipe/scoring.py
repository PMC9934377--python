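"""Log-odds-ratio partial risk scores and threshold calibration.

Each feature ``i`` gets a partial risk score

    PRS_i = ln[ (cases_with_i / cases_without_i)
              / (controls_with_i / controls_without_i) ]

i.e. the natural-log odds ratio of ever being coded with the feature among
cases versus controls; negative scores are protective, positive adverse.
A patient's total score is the plain sum of PRS over the distinct features
present — a Naive-Bayes log-posterior up to the constant class prior,
which shifts every patient equally and therefore cancels in thresholding
and ranking.

Classification thresholds are percentiles of the training controls' score
distribution chosen so the achieved training specificity is at least the
benchmark (90%, 95%, ...) even under ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MODEL_COLUMNS = [
    "key", "cases_with", "cases_without", "controls_with", "controls_without",
    "odds_ratio", "prs", "smoothed",
]


def _or_core(
    cases_with: float, cases_without: float,
    controls_with: float, controls_without: float,
) -> tuple[float, bool]:
    cells = (cases_with, cases_without, controls_with, controls_without)
    if any(c < 0 for c in cells):
        raise ValueError("contingency counts must be nonnegative")
    if cases_with + cases_without <= 0 or controls_with + controls_without <= 0:
        raise ValueError("both margin rows must have positive totals")
    smoothed = any(c == 0 for c in cells)
    if smoothed:
        # Haldane-Anscombe continuity correction on all four cells
        cells = tuple(c + 0.5 for c in cells)
    a, b, c, d = cells
    return (a / b) / (c / d), smoothed


def odds_ratio(
    cases_with: float, cases_without: float,
    controls_with: float, controls_without: float,
) -> float:
    """2x2 odds ratio (a/b)/(c/d), +0.5 on every cell iff any cell is zero."""
    return _or_core(cases_with, cases_without, controls_with, controls_without)[0]


def odds_ratio_flagged(
    cases_with: float, cases_without: float,
    controls_with: float, controls_without: float,
) -> tuple[float, bool]:
    """Like :func:`odds_ratio`, also reporting whether smoothing applied."""
    return _or_core(cases_with, cases_without, controls_with, controls_without)


@dataclass(frozen=True)
class RiskModel:
    """Fitted per-feature scores with their underlying patient counts."""

    table: pd.DataFrame
    n_cases: int
    n_controls: int

    @property
    def prs(self) -> pd.Series:
        return self.table.set_index("key")["prs"]

    def prs_map(self) -> dict[str, float]:
        return dict(zip(self.table["key"], self.table["prs"]))


def fit_prs(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    vocabulary: pd.DataFrame,
) -> RiskModel:
    """Fit one PRS per vocabulary feature from training-arm patient counts.

    ``features`` is the long training-arm feature frame; counts are
    distinct-patient (ever-coded) counts, never event counts.  Zero cells
    are handled by the same continuity correction as :func:`odds_ratio`,
    keeping every score finite.
    """
    lab = labels.set_index("patient_id")["is_case"]
    n_cases = int(lab.sum())
    n_controls = int((~lab).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("training arm needs at least one case and one control")

    present = features.drop_duplicates(["patient_id", "key"]).copy()
    present["is_case"] = present["patient_id"].map(lab)
    present = present[present["is_case"].notna()]
    by_key = present.groupby("key")["is_case"]
    cases_with = by_key.sum().astype(int)
    total_with = by_key.size()

    tbl = vocabulary[["key"]].copy()
    tbl["cases_with"] = tbl["key"].map(cases_with).fillna(0).astype(int)
    tbl["controls_with"] = (
        tbl["key"].map(total_with).fillna(0).astype(int) - tbl["cases_with"]
    )
    tbl["cases_without"] = n_cases - tbl["cases_with"]
    tbl["controls_without"] = n_controls - tbl["controls_with"]

    a = tbl["cases_with"].to_numpy(float)
    b = tbl["cases_without"].to_numpy(float)
    c = tbl["controls_with"].to_numpy(float)
    d = tbl["controls_without"].to_numpy(float)
    smoothed = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a2, b2, c2, d2 = (x + 0.5 * smoothed for x in (a, b, c, d))
    tbl["odds_ratio"] = (a2 / b2) / (c2 / d2)
    tbl["prs"] = np.log(tbl["odds_ratio"])
    tbl["smoothed"] = smoothed
    return RiskModel(tbl[MODEL_COLUMNS], n_cases=n_cases, n_controls=n_controls)


def total_score(feature_keys: Iterable[str], model: RiskModel | Mapping[str, float]) -> float:
    """Sum of PRS over the distinct present features; unknown features add 0."""
    prs = model.prs_map() if isinstance(model, RiskModel) else dict(model)
    return float(sum(prs.get(k, 0.0) for k in set(feature_keys)))


@dataclass(frozen=True)
class ThresholdSet:
    """Specificity-target -> cutoff score; classification is score > cutoff."""

    cutoffs: dict[float, float]

    def __getitem__(self, target: float) -> float:
        return self.cutoffs[target]

    def items(self):
        return self.cutoffs.items()


def select_thresholds(
    control_scores: Sequence[float],
    specificity_targets: Sequence[float] = (0.90, 0.95),
) -> ThresholdSet:
    """Percentile cutoffs of the training controls' scores.

    For each target q the cutoff is the smallest observed control score s
    such that the fraction of control scores strictly above s is at most
    1 - q; with the strictly-greater-than classification rule this
    guarantees achieved training specificity >= q even under ties.
    Requires at least 20 control scores.
    """
    scores = np.sort(np.asarray(list(control_scores), dtype=float))
    n = scores.size
    if n < 20:
        raise ValueError(f"need >= 20 control scores to calibrate, got {n}")
    uniq = np.unique(scores)
    n_greater = n - np.searchsorted(scores, uniq, side="right")
    cutoffs: dict[float, float] = {}
    for q in specificity_targets:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"specificity target {q} outside [0, 1]")
        ok = n_greater <= (1.0 - q) * n + 1e-9
        cutoffs[float(q)] = float(uniq[np.argmax(ok)])
    return ThresholdSet(cutoffs)


def z_scale_ors(or_values: Sequence[float]) -> np.ndarray:
    """Affine-scale an OR vector to mean 0 / sample SD 1 (Z units).

    Used to compare feature rankings across cohorts of very different
    size, where the raw OR scales differ.  Raises on vectors shorter than
    2 or with zero spread.
    """
    x = np.asarray(list(or_values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to Z-scale")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot Z-scale a constant vector (zero SD)")
    return (x - x.mean()) / sd
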