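"""Simulate the marker-cohort registry extract used by the downstream steps.

Generates a synthetic cohort of 15,000 patients who all carry the
subpopulation marker diagnosis (code 340), with ~1.3% lifetime prevalence
of the case-defining outcome, planted shared risk/protective codes, and
both exclusion mechanisms switched on (a fraction of cases with no
documentation before the event, and a fraction whose marker is recorded
only after the event) so the cohort-building step has realistic work to
do.  Tables are written as plain CSV under scratch/cohort/.

Run: python analysis/01_simulate_cohort.py [--seed 42]
"""

import argparse
from pathlib import Path

from riskpipe import io
from riskpipe.synthetic import SimConfig, generate_cohort

OUT = Path("scratch/cohort")


def cohort_config(seed: int) -> SimConfig:
    return SimConfig(
        n_patients=15_000,
        subpop_fraction=1.0,
        baseline_prevalence=0.013,
        events_per_year=6.0,
        no_history_case_frac=0.14,
        marker_after_event_frac=0.20,
        seed=seed,
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    res = generate_cohort(cohort_config(args.seed))
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_event_table(res.events, OUT / "events.csv")
    io.write_demographics(res.demographics, OUT / "demographics.csv")
    io.write_truth(res.truth, OUT / "truth.csv")
    res.planted_effects.to_csv(OUT / "planted_effects.csv", index=False)

    n = len(res.truth)
    n_cases = int(res.truth["is_case"].sum())
    print(f"simulated {n} patients, {len(res.events)} coded events")
    print(f"cases: {n_cases} ({100 * n_cases / n:.1f}% prevalence)")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
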