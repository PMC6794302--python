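#!/usr/bin/env python
"""Merge editions and reduce admissions to first-diagnosis timelines.

Applies the deceased-only merge rule (latest edition in full, earlier
editions contribute deceased patients only), truncates diagnoses to the
three-digit chapter level, drops non-disease principal diagnoses
(pregnancy/childbirth, injury/poisoning, external causes, administrative
codes), and collapses readmissions to the first occurrence per code.
Writes the per-category filtering report and a timeline summary.
"""

import argparse
import json
from pathlib import Path

from trajmine.preprocess import MergePolicy, merge_editions, prepare_timelines
from trajmine.records import read_admissions

OUT = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    records = read_admissions(OUT / "registry.csv")
    latest = max(r.edition_id for r in records)
    merged = merge_editions(records, MergePolicy(latest_edition=latest))
    timelines, report = prepare_timelines(merged)

    n_deaths = sum(tl.death_day is not None for tl in timelines)
    summary = {
        "admissions_raw": len(records),
        "admissions_after_merge": len(merged),
        "dropped_nondisease": report,
        "patients": len(timelines),
        "patients_with_death": n_deaths,
        "distinct_codes": len({c for tl in timelines for c in tl.first_dx_day}),
    }
    (OUT / "preprocess_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"{len(records)} raw admissions -> {len(merged)} after merge "
          f"(latest edition {latest})")
    print(f"dropped as non-disease: {report}")
    print(f"{len(timelines)} patient timelines, {n_deaths} with an in-hospital death")


if __name__ == "__main__":
    main()
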