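"""Fit the log-odds-ratio scoring model and validate it prospectively.

Splits the included cohort in half, learns one partial risk score (natural
log odds ratio) per ever-coded feature on the training arm, calibrates
cutoffs at the 90% and 95% percentiles of the training controls' overall
risk scores, and replays each test patient chronologically: cumulative
score Risk_t, overall score ORS = max_t Risk_t, threshold classification,
ROC/AUC, and lead times for detected cases.  Outputs under results/.

Run after 01: python analysis/03_fit_and_validate.py [--split-seed 7]
"""

import argparse
from pathlib import Path

from riskpipe import io, pipeline

IN = Path("scratch/cohort")
OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--split-seed", type=int, default=7)
    args = ap.parse_args()

    events = io.read_event_table(IN / "events.csv")
    demographics = io.read_demographics(IN / "demographics.csv")
    res = pipeline.run_pipeline(events, demographics, split_seed=args.split_seed)

    OUT.mkdir(exist_ok=True)
    io.write_vocabulary(res.fitted.vocabulary, OUT / "vocabulary.tsv")
    io.write_risk_model(res.fitted.model.table, OUT / "risk_model.tsv")
    io.write_metric_panel(res.panel, OUT / "metric_panel.tsv")
    res.lead.to_csv(OUT / "lead_times.tsv", sep="\t", index=False)

    from riskpipe.validation import roc_points

    test_labels = res.labels.set_index("patient_id").loc[res.test_ors.index]
    roc_points(res.test_ors.to_numpy(), test_labels["is_case"].to_numpy(bool)).to_csv(
        OUT / "roc_points.csv", index=False
    )

    tbl = res.fitted.model.table
    print(f"vocabulary: {len(res.fitted.vocabulary)} features; "
          f"training arm n = {res.fitted.n_train}")
    top = tbl.sort_values("prs", ascending=False).head(5)
    bottom = tbl.sort_values("prs").head(3)
    print("strongest adverse features (key, OR, PRS):")
    for _, r in top.iterrows():
        print(f"  {r['key']:<18} OR {r['odds_ratio']:6.2f}  PRS {r['prs']:+.2f}")
    print("strongest protective features:")
    for _, r in bottom.iterrows():
        print(f"  {r['key']:<18} OR {r['odds_ratio']:6.2f}  PRS {r['prs']:+.2f}")

    print(f"\nvalidation AUC = {res.auc:.2f}")
    cols = ["spec_target", "spec_pct", "sens_pct", "ppv_pct", "npv_pct",
            "tp", "tn", "fp", "fn", "lr_pos_rounded", "lr_neg_rounded"]
    print(res.panel[cols].to_string(index=False))
    for _, r in res.lead.iterrows():
        print(
            f"at {r['spec_target']:.0%} target specificity: detected "
            f"{r['n_detected']} cases, mean lead {r['mean_lead_years']:.1f} y"
        )


if __name__ == "__main__":
    main()
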