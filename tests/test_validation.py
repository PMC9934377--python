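"""Prospective replay: trajectories, classification, metric panels, ROC, leads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskpipe import validation
from riskpipe.scoring import ThresholdSet
from riskpipe.synthetic import EPOCH
from riskpipe.validation import (
    build_trajectory,
    classify,
    lead_times,
    metric_panel,
    metrics_from_counts,
    roc_auc,
    roc_points,
    trajectory_table,
)

from conftest import pairwise_auc


def day(d):
    return EPOCH + pd.Timedelta(days=d)


def feats(rows):
    """(patient_id, key, day) -> extracted-feature frame."""
    df = pd.DataFrame(rows, columns=["patient_id", "key", "d"])
    df["first_date"] = df.pop("d").map(day)
    return df


class _FakeModel:
    """Minimal stand-in exposing the RiskModel.prs surface."""

    def __init__(self, mapping):
        self.prs = pd.Series(mapping)


MODEL = _FakeModel({"A": 1.0, "B": -2.0, "C": 3.0})


class TestTrajectory:
    def test_running_sum_and_maximum(self):
        t = build_trajectory(
            feats([("p", "A", 1), ("p", "B", 2), ("p", "C", 3)]), MODEL
        )
        assert list(t.risk) == [1.0, -1.0, 2.0]
        assert t.ors == 2.0

    def test_same_day_features_aggregate_before_emitting(self):
        t = build_trajectory(
            feats([("p", "A", 1), ("p", "B", 1), ("p", "C", 1)]), MODEL
        )
        assert list(t.risk) == [2.0]
        assert t.ors == 2.0

    def test_first_occurrence_only(self):
        """A variable recurring later adds nothing: extraction collapses it to
        its first date, and the day-5 cumulative value equals day-1's."""
        t = build_trajectory(feats([("p", "A", 1), ("p", "D", 5)]),
                             _FakeModel({"A": 1.0}))
        assert list(t.risk) == [1.0, 1.0]

    def test_empty_record_convention(self):
        t = build_trajectory(feats([]), MODEL, patient_id="p")
        assert t.empty and t.ors == 0.0

    def test_within_day_order_invariance(self):
        rows = [("p", "A", 2), ("p", "B", 2), ("p", "C", 1)]
        a = build_trajectory(feats(rows), MODEL)
        b = build_trajectory(feats(rows[::-1]), MODEL)
        assert list(a.risk) == list(b.risk)
        assert a.ors == b.ors

    def test_out_of_vocabulary_contributes_zero_but_keeps_date(self):
        t = build_trajectory(feats([("p", "ZZZ", 1), ("p", "A", 4)]), MODEL)
        assert list(t.risk) == [0.0, 1.0]

    def test_first_crossing(self):
        t = build_trajectory(
            feats([("p", "A", 1), ("p", "B", 2), ("p", "C", 3)]), MODEL
        )
        assert t.first_crossing(0.5) == day(1)
        assert t.first_crossing(1.5) == day(3)
        assert t.first_crossing(10.0) is None


class TestClassify:
    def test_strictly_greater_rule(self):
        ts = ThresholdSet({0.9: 2.0})
        assert not classify(2.0, ts)[0.9]
        assert classify(2.0 + 1e-9, ts)[0.9]
        assert not classify(0.0, ts)[0.9]


class TestMetricPanel:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,sens,spec,ppv,npv,lrp,lrn",
        [
            (1, 7433, 75, 51, 2, 99, 1, 99, 2.00, 0.99),
            (12, 7133, 375, 40, 23, 95, 3, 99, 4.60, 0.81),
            (19, 6757, 751, 33, 37, 90, 2, 100, 3.70, 0.70),
            (33, 6006, 1502, 19, 63, 80, 2, 100, 3.15, 0.46),
            (47, 3594, 3914, 5, 90, 48, 1, 100, 1.73, 0.21),
        ],
    )
    def test_reference_operating_points(self, tp, tn, fp, fn, sens, spec, ppv,
                                        npv, lrp, lrn):
        """Confusion counts reproduce the integer-percent metric convention and
        the likelihood ratios recomputed from those integer percents."""
        m = metrics_from_counts(tp, tn, fp, fn)
        assert (m["sens_pct"], m["spec_pct"]) == (sens, spec)
        assert (m["ppv_pct"], m["npv_pct"]) == (ppv, npv)
        assert m["lr_pos_rounded"] == pytest.approx(lrp)
        assert m["lr_neg_rounded"] == pytest.approx(lrn)

    def test_exact_and_rounded_lr_variants_differ(self):
        m = metrics_from_counts(19, 6757, 751, 33)
        assert m["lr_pos"] == pytest.approx(3.653, abs=1e-3)
        assert m["lr_pos_rounded"] == pytest.approx(3.70)

    def test_ppv_undefined_sentinel(self):
        m = metrics_from_counts(0, 90, 0, 10)
        assert np.isnan(m["ppv"]) and m["ppv_pct"] is None

    def test_row_sums_conserved_across_thresholds(self):
        rng = np.random.default_rng(7)
        ors = pd.Series(rng.normal(size=300),
                        index=[f"p{i}" for i in range(300)])
        labels = pd.DataFrame(
            {"patient_id": ors.index, "is_case": rng.random(300) < 0.1}
        )
        n_cases = int(labels["is_case"].sum())
        panel = metric_panel(ors, labels, ThresholdSet({0.8: -1.0, 0.9: 0.0, 0.95: 1.0}))
        assert (panel["tp"] + panel["fn"] == n_cases).all()
        assert (panel["tn"] + panel["fp"] == 300 - n_cases).all()

    def test_perfect_separation(self):
        ors = pd.Series([5.0, 6.0, 1.0, 2.0], index=list("abcd"))
        labels = pd.DataFrame(
            {"patient_id": list("abcd"), "is_case": [True, True, False, False]}
        )
        panel = metric_panel(ors, labels, ThresholdSet({0.9: 3.0}))
        assert panel["sensitivity"].iloc[0] == 1.0
        assert panel["specificity"].iloc[0] == 1.0


class TestRocAuc:
    def test_perfectly_separated(self):
        assert roc_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_all_tied_is_chance(self):
        assert roc_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5

    def test_small_tie_case_by_hand(self):
        # cases {2,3,3} vs controls {1,3,4}: (wins + half-ties)/9 = 4/9
        assert roc_auc([2, 3, 3, 1, 3, 4],
                       [True, True, True, False, False, False]) == pytest.approx(4 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_pairwise_oracle_on_random_instances(self):
        """Rank-form AUC equals the brute-force pairwise concordance count
        exactly on 100 random instances (with ties)."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 12, n).astype(float)  # heavy ties
            y = rng.random(n) < rng.uniform(0.1, 0.9)
            if y.all() or not y.any():
                continue
            assert roc_auc(scores, y) == pytest.approx(pairwise_auc(scores, y),
                                                       abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=400)
        y = rng.random(400) < 0.2
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_negating_scores_flips_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 50).astype(float)
        y = np.zeros(50, bool)
        y[:7] = True
        assert roc_auc(-scores, y) == pytest.approx(1 - roc_auc(scores, y))

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(11)
        pts = roc_points(rng.normal(size=100), rng.random(100) < 0.3)
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()
        assert pts["fpr"].iloc[-1] == 1.0 and pts["tpr"].iloc[-1] == 1.0


class TestLeadTimes:
    def _setup(self, cross_day, event_day_, risk=3.0):
        traj = pd.DataFrame(
            {"patient_id": ["c"], "date": [day(cross_day)], "risk": [risk]}
        )
        labels = pd.DataFrame(
            {"patient_id": ["c"], "is_case": [True],
             "first_event_date": [day(event_day_)]}
        )
        return traj, labels

    def test_two_year_lead(self):
        traj, labels = self._setup(0, 730)
        out = lead_times(traj, labels, ThresholdSet({0.9: 1.0}))
        assert out["n_detected"].iloc[0] == 1
        assert out["mean_lead_years"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_undetected_case_excluded(self):
        traj, labels = self._setup(0, 730, risk=0.5)
        out = lead_times(traj, labels, ThresholdSet({0.9: 1.0}))
        assert out["n_detected"].iloc[0] == 0
        assert np.isnan(out["mean_lead_years"].iloc[0])

    def test_leads_positive_on_pipeline_output(self, small_pipeline):
        """Censoring guarantees crossings precede events, so every computed
        lead is positive."""
        lead = small_pipeline.lead
        detected = lead[lead["n_detected"] > 0]
        assert not detected.empty
        assert (detected["mean_lead_years"] > 0).all()
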