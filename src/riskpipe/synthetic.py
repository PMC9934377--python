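"""Synthetic longitudinal coded-EHR cohorts with planted case/control structure.

The generator emulates a registry extract: one row per patient-date-code
event (diagnoses DX, medications RX, lab flags LAB), a demographics table,
and a per-patient truth record.  Case status is drawn from a logistic model
over ever-coded indicator features, so the generative family matches the
prevalence-based (ever-coded) scoring model fitted downstream.  A
configurable fraction of patients belongs to a marked subpopulation
(diagnosis code 340 as the marker, by analogy with multiple sclerosis);
subpopulation-specific planted codes carry their effect only inside that
subpopulation, which is what the subpopulation-trained vs general-trained
model comparison exploits.

Conventions
-----------
* Dates are whole days on a single calendar anchored at :data:`EPOCH`;
  every patient's follow-up starts at day 0.
* Cases receive the case-defining code (``E9500``) at their event date and
  all other generated events are dated strictly before it, so a case's
  record ends at the event.  The one documented exception is the
  subpopulation marker, which ``marker_after_event_frac`` can place after
  the event: a marker diagnosis keeps being recorded in a real registry
  even when analysis data are censored at the event, and temporal-ordering
  exclusions downstream need such patients to exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

EPOCH = pd.Timestamp("2000-01-01")
MARKER_CODE = "340"
CASE_CODE = "E9500"

EVENT_COLUMNS = ["patient_id", "date", "code_type", "code", "value_flag"]
DEMO_COLUMNS = ["patient_id", "sex", "birth_year", "race", "marital_status"]

_LAB_FLAGS = np.array(["L", "N", "H"])


class PrevalenceError(ValueError):
    """The requested marginal prevalence cannot be reached by any intercept."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a registry-like marker cohort: 15,000 patients, 1.3%
    lifetime prevalence of the case-defining outcome, mean follow-up 8.4
    years, and planted shared effects whose log odds ratios and control
    base rates span the range seen for coded suicide-risk factors
    (strong adverse ~e^2.6, moderate ~e^1.4, and weakly protective codes).

    Parameters
    ----------
    n_patients : cohort size.
    subpop_fraction : probability a patient carries the subpopulation
        marker code (1.0 = a pure marker cohort; <1 for a general cohort
        containing the subpopulation).
    baseline_prevalence : target marginal probability of being a case; the
        model intercept is solved numerically so the realized expectation
        matches it.
    shared_effects / shared_base_rates : per-code true log odds ratio and
        control ever-coded probability for codes whose effect applies to
        everyone.
    subpop_effects / subpop_base_rates : same for codes coded in everyone
        but causally active only inside the subpopulation.
    n_noise_codes : number of null codes (mixed DX/RX/LAB) drawn at an
        overall rate of ``events_per_year`` coded events per follow-up year.
    followup_mean_years / followup_sd_years : gamma-distributed per-patient
        follow-up length.
    no_history_case_frac : fraction of cases whose case-defining event
        lands on their first follow-up day while their coded record keeps
        going afterwards, leaving no documentation prior to the event
        (exercises the no-prior-data exclusion downstream; like the marker
        toggle, a deliberate exception to generator-level truncation).
    marker_after_event_frac : fraction of subpopulation *cases* whose
        marker is dated after the case event (exercises the
        event-before-marker exclusion downstream).
    seed : RNG seed; a fixed config is byte-for-byte reproducible.
    """

    n_patients: int = 15_000
    subpop_fraction: float = 1.0
    baseline_prevalence: float = 0.013
    shared_effects: tuple[float, ...] = (2.6, 2.1, 1.8, 1.5, 1.4, 1.0, -0.1, -0.5)
    shared_base_rates: tuple[float, ...] = (
        0.008, 0.014, 0.043, 0.049, 0.087, 0.25, 0.286, 0.143,
    )
    subpop_effects: tuple[float, ...] = (1.5, 1.2, -0.4)
    subpop_base_rates: tuple[float, ...] = (0.05, 0.08, 0.10)
    n_noise_codes: int = 200
    followup_mean_years: float = 8.4
    followup_sd_years: float = 4.0
    events_per_year: float = 10.0
    no_history_case_frac: float = 0.0
    marker_after_event_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        for name in ("subpop_fraction", "baseline_prevalence",
                     "no_history_case_frac", "marker_after_event_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie strictly in (0, 1)")
        if len(self.shared_effects) != len(self.shared_base_rates):
            raise ValueError("shared_effects and shared_base_rates lengths differ")
        if len(self.subpop_effects) != len(self.subpop_base_rates):
            raise ValueError("subpop_effects and subpop_base_rates lengths differ")
        for rates in (self.shared_base_rates, self.subpop_base_rates):
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError("base rates must lie in [0, 1]")
        for effs in (self.shared_effects, self.subpop_effects):
            if any(not np.isfinite(e) for e in effs):
                raise ValueError("effects must be finite")
        if self.n_noise_codes < 0:
            raise ValueError("n_noise_codes must be nonnegative")
        if self.followup_mean_years <= 0 or self.followup_sd_years <= 0:
            raise ValueError("follow-up distribution parameters must be positive")
        if self.events_per_year < 0:
            raise ValueError("events_per_year must be nonnegative")

    @property
    def n_shared_risk_codes(self) -> int:
        return len(self.shared_effects)

    @property
    def n_subpop_risk_codes(self) -> int:
        return len(self.subpop_effects)

    @property
    def shared_codes(self) -> list[str]:
        return [f"SH{i:02d}" for i in range(self.n_shared_risk_codes)]

    @property
    def subpop_codes(self) -> list[str]:
        return [f"SP{i:02d}" for i in range(self.n_subpop_risk_codes)]


@dataclass(frozen=True)
class SimResult:
    """Output bundle of :func:`generate_cohort`.

    ``truth`` holds one row per patient (``is_case``, ``is_subpop``,
    ``event_date`` set iff case) plus one boolean ``has_<code>`` column per
    planted code — the ground-truth ever-coded indicators that drove case
    generation, usable as an exact 2x2 oracle.  ``planted_effects`` maps
    each planted code to its true log odds ratio and base rate.
    """

    events: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    planted_effects: pd.DataFrame

    def __iter__(self):
        return iter((self.events, self.demographics, self.truth))


def _noise_code_type(idx: np.ndarray) -> np.ndarray:
    """Deterministic DX/RX/LAB assignment for noise code ids (3:1:1 mix)."""
    out = np.where(idx % 5 < 3, "DX", np.where(idx % 5 == 3, "RX", "LAB"))
    return out


def solve_intercept(linear_predictor: np.ndarray, target_prevalence: float) -> float:
    """Intercept b with mean(expit(b + lp)) equal to the target prevalence."""

    def gap(b: float) -> float:
        return float(np.mean(expit(b + linear_predictor))) - target_prevalence

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise PrevalenceError(
            f"target prevalence {target_prevalence} unreachable: attainable range "
            f"[{np.mean(expit(lo + linear_predictor)):.3g}, "
            f"{np.mean(expit(hi + linear_predictor)):.3g}]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _empty_result(config: SimConfig) -> SimResult:
    events = pd.DataFrame(columns=EVENT_COLUMNS).astype(
        {"patient_id": str, "code_type": str, "code": str, "value_flag": str}
    )
    events["date"] = pd.to_datetime(events["date"])
    demographics = pd.DataFrame(columns=DEMO_COLUMNS)
    truth_cols = (
        ["patient_id", "is_case", "is_subpop", "event_date"]
        + [f"has_{c}" for c in config.shared_codes + config.subpop_codes]
    )
    truth = pd.DataFrame(columns=truth_cols)
    return SimResult(events, demographics, truth, planted_effects(config))


def planted_effects(config: SimConfig) -> pd.DataFrame:
    """Table of planted codes with scope, true log-OR, and base rate."""
    rows = [
        ("SH%02d" % i, "shared", e, r)
        for i, (e, r) in enumerate(zip(config.shared_effects, config.shared_base_rates))
    ] + [
        ("SP%02d" % i, "subpop", e, r)
        for i, (e, r) in enumerate(zip(config.subpop_effects, config.subpop_base_rates))
    ]
    return pd.DataFrame(rows, columns=["code", "scope", "log_or", "base_rate"])


def generate_cohort(config: SimConfig) -> SimResult:
    """Generate a dated event table, demographics, and truth records.

    Case status is Bernoulli with logit equal to the sum of true log-OR
    effects over the patient's ever-coded planted indicators (subpop
    effects contribute only for subpopulation members) plus an intercept
    solved so the realized mean case probability equals
    ``baseline_prevalence``.  Cases get the case-defining code at an event
    date uniform over the second half of their follow-up and no other
    events on or after that date.
    """
    if config.n_patients == 0:
        return _empty_result(config)

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = np.array([f"P{i:07d}" for i in range(n)])

    is_subpop = rng.random(n) < config.subpop_fraction

    mean, sd = config.followup_mean_years, config.followup_sd_years
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    followup_years = np.clip(rng.gamma(shape, scale, n), 0.25, 40.0)
    followup_days = np.maximum((followup_years * 365.25).astype(np.int64), 30)

    shared_rates = np.asarray(config.shared_base_rates)
    subpop_rates = np.asarray(config.subpop_base_rates)
    has_shared = rng.random((n, len(shared_rates))) < shared_rates
    has_subpop = rng.random((n, len(subpop_rates))) < subpop_rates

    lp = has_shared @ np.asarray(config.shared_effects)
    if len(config.subpop_effects):
        lp = lp + (has_subpop @ np.asarray(config.subpop_effects)) * is_subpop

    intercept = solve_intercept(lp, config.baseline_prevalence)
    is_case = rng.random(n) < expit(intercept + lp)

    # case event in the second half of follow-up so pre-event history exists
    event_day = np.full(n, -1, dtype=np.int64)
    case_idx = np.flatnonzero(is_case)
    if case_idx.size:
        half = followup_days[case_idx] // 2
        event_day[case_idx] = half + (
            rng.random(case_idx.size) * (followup_days[case_idx] - half)
        ).astype(np.int64)
    forced = np.array([], dtype=np.int64)
    if case_idx.size and config.no_history_case_frac > 0:
        forced = case_idx[rng.random(case_idx.size) < config.no_history_case_frac]
        event_day[forced] = 0
    # generated history strictly precedes the event for cases; forced
    # no-history cases instead keep a full record that starts AT the event,
    # so they carry enough visits to reach the documentation filter
    limit_day = np.where(is_case, event_day, followup_days)
    limit_day[forced] = followup_days[forced]

    pid_parts: list[np.ndarray] = []
    day_parts: list[np.ndarray] = []
    type_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    flag_parts: list[np.ndarray] = []

    def emit(p: np.ndarray, d: np.ndarray, t: np.ndarray, c: np.ndarray,
             f: np.ndarray) -> None:
        pid_parts.append(p)
        day_parts.append(d)
        type_parts.append(t)
        code_parts.append(c)
        flag_parts.append(f)

    # planted code events: one dated record per present code, strictly pre-limit
    planted_names = config.shared_codes + config.subpop_codes
    has_planted = np.hstack([has_shared, has_subpop]) if planted_names else \
        np.zeros((n, 0), dtype=bool)
    for j, code in enumerate(planted_names):
        carrier = np.flatnonzero(has_planted[:, j] & (limit_day > 0))
        if carrier.size == 0:
            continue
        days = (rng.random(carrier.size) * limit_day[carrier]).astype(np.int64)
        emit(pids[carrier], days,
             np.full(carrier.size, "DX"), np.full(carrier.size, code),
             np.full(carrier.size, ""))

    # subpopulation marker events
    sub_idx = np.flatnonzero(is_subpop & (limit_day > 0))
    if sub_idx.size:
        marker_day = (rng.random(sub_idx.size) * limit_day[sub_idx]).astype(np.int64)
        if config.marker_after_event_frac > 0:
            sub_case = is_case[sub_idx]
            flip = sub_case & (rng.random(sub_idx.size) < config.marker_after_event_frac)
            lo = event_day[sub_idx] + 1
            hi = np.maximum(followup_days[sub_idx], lo + 1)
            late = lo + (rng.random(sub_idx.size) * (hi - lo)).astype(np.int64)
            marker_day = np.where(flip, late, marker_day)
        emit(pids[sub_idx], marker_day,
             np.full(sub_idx.size, "DX"), np.full(sub_idx.size, MARKER_CODE),
             np.full(sub_idx.size, ""))

    # background noise events at events_per_year over the observed record
    if config.n_noise_codes > 0 and config.events_per_year > 0:
        lam = config.events_per_year * limit_day / 365.25
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total:
            owner = np.repeat(np.arange(n), counts)
            code_ids = rng.integers(0, config.n_noise_codes, total)
            days = (rng.random(total) * limit_day[owner]).astype(np.int64)
            ctypes = _noise_code_type(code_ids)
            flags = np.where(ctypes == "LAB", _LAB_FLAGS[rng.integers(0, 3, total)], "")
            codes = np.char.add("NZ", np.char.zfill(code_ids.astype(str), 3))
            emit(pids[owner], days, ctypes, codes, flags)

    # the case-defining event itself
    if case_idx.size:
        emit(pids[case_idx], event_day[case_idx],
             np.full(case_idx.size, "DX"), np.full(case_idx.size, CASE_CODE),
             np.full(case_idx.size, ""))

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_parts) if pid_parts else np.array([], str),
            "date": EPOCH
            + pd.to_timedelta(
                np.concatenate(day_parts) if day_parts else np.array([], np.int64),
                unit="D",
            ),
            "code_type": np.concatenate(type_parts) if type_parts else np.array([], str),
            "code": np.concatenate(code_parts) if code_parts else np.array([], str),
            "value_flag": np.concatenate(flag_parts) if flag_parts else np.array([], str),
        }
    )
    events = events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)

    age_at_epoch = rng.integers(18, 81, n)
    demographics = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": rng.choice(["F", "M"], n, p=[0.73, 0.27]),
            "birth_year": EPOCH.year - age_at_epoch,
            "race": rng.choice(
                ["White", "Black", "Hispanic", "Asian", "Other"],
                n, p=[0.78, 0.05, 0.03, 0.01, 0.13],
            ),
            "marital_status": rng.choice(
                ["Married", "Single", "Divorced", "Widowed", "Other"],
                n, p=[0.56, 0.27, 0.08, 0.04, 0.05],
            ),
        }
    )

    truth = pd.DataFrame(
        {"patient_id": pids, "is_case": is_case, "is_subpop": is_subpop}
    )
    truth["event_date"] = pd.NaT
    if case_idx.size:
        truth.loc[case_idx, "event_date"] = EPOCH + pd.to_timedelta(
            event_day[case_idx], unit="D"
        )
    for j, code in enumerate(planted_names):
        truth[f"has_{code}"] = has_planted[:, j]

    return SimResult(events, demographics, truth, planted_effects(config))


def empirical_log_or(truth: pd.DataFrame, code: str) -> float:
    """Exact 2x2 ever-coded log odds ratio of a planted code from truth records.

    Serves as the generator-level oracle for planted-effect recovery; it
    counts ground-truth presence indicators, not the fitted model's counts.
    """
    has = truth[f"has_{code}"].to_numpy(bool)
    case = truth["is_case"].to_numpy(bool)
    a = int((has & case).sum())
    b = int((~has & case).sum())
    c = int((has & ~case).sum())
    d = int((~has & ~case).sum())
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float(np.log((a / b) / (c / d)))
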