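"""Apply the case definition and cohort filters to the simulated extract.

Reads scratch/cohort/, finds cases by diagnosis-code prefix (E95*, 965*,
967*, 969*, 881*), applies the three inclusion criteria, excludes cases
without pre-event documentation and cases whose event precedes the marker
diagnosis, and reports the exclusion accounting, the marker/event
temporal ordering, and a demographics summary.  Labels go to
results/cohort_labels.csv.

Run after 01: python analysis/02_build_cohort.py
"""

import json
from pathlib import Path

from riskpipe import cohort, io, pipeline

IN = Path("scratch/cohort")
OUT = Path("results")


def main() -> None:
    events = io.read_event_table(IN / "events.csv")
    demographics = io.read_demographics(IN / "demographics.csv")

    labels = pipeline.build_labels(events, demographics)
    OUT.mkdir(exist_ok=True)
    io.write_labels(labels, OUT / "cohort_labels.csv")

    acc = cohort.exclusion_accounting(labels)
    order = cohort.classify_temporal_order(labels)
    n_cases = sum(order.values())
    included = int(labels["included"].sum())
    n_controls = included - acc["cases_included"]

    print("case accounting:", json.dumps(acc))
    print(
        f"identified {acc['cases_identified']} cases; excluded "
        f"{acc['no_prior_data']} without prior documentation and "
        f"{acc['event_before_marker']} with the event before the marker; "
        f"{acc['cases_included']} cases and {n_controls} controls analyzed "
        f"({100 * acc['cases_included'] / included:.1f}% prevalence)"
    )
    print(
        "temporal order among cases: "
        + ", ".join(f"{k} {v} ({100 * v / n_cases:.0f}%)" for k, v in order.items())
    )

    summary = cohort.summarize_demographics(labels, demographics)
    summary.table.to_csv(OUT / "demographics_summary.csv", index=False)
    print(f"women:men ratio = {summary.sex_ratio['all']:.1f}:1")
    (OUT / "cohort_accounting.json").write_text(
        json.dumps({"accounting": acc, "temporal_order": order,
                    "sex_ratio": summary.sex_ratio}, indent=2)
    )


if __name__ == "__main__":
    main()
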