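#!/usr/bin/env python
"""Cohort-level validation of the planted schizophrenia → muscle-disorder link.

From the simulated timelines, builds the 2×2 table of muscle-disorder
(728) outcomes among patients with vs without a schizophrenia (295)
diagnosis and reports the relative risk with 95% CI, the hypergeometric
enrichment of muscle-disorder cases among schizophrenia patients, and
the rate of the outcome in the exposed cohort with its fold over the
cohort-wide rate — the same statistics used to validate comorbidity
signals on real cohorts.
"""

import argparse
import json
from pathlib import Path

from trajmine.preprocess import MergePolicy, prepare_timelines
from trajmine.records import read_admissions
from trajmine.stats import TwoByTwo, hypergeom_enrichment, rate_report, relative_risk

OUT = Path("results/analysis")
EXPOSURE, OUTCOME = "295", "728"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    records = read_admissions(OUT / "registry.csv")
    policy = MergePolicy(latest_edition=max(r.edition_id for r in records))
    timelines, _ = prepare_timelines(records, policy)

    # outcome after exposure, in time order, as on a real cohort
    exposed = [tl for tl in timelines if EXPOSURE in tl.first_dx_day]
    unexposed = [tl for tl in timelines if EXPOSURE not in tl.first_dx_day]
    a = sum(
        1
        for tl in exposed
        if OUTCOME in tl.first_dx_day
        and tl.first_dx_day[OUTCOME] > tl.first_dx_day[EXPOSURE]
    )
    b = len(exposed) - a
    c = sum(1 for tl in unexposed if OUTCOME in tl.first_dx_day)
    d = len(unexposed) - c

    rr = relative_risk(TwoByTwo(a, b, c, d))
    n_outcome = sum(1 for tl in timelines if OUTCOME in tl.first_dx_day)
    p_enrich = hypergeom_enrichment(
        population=len(timelines),
        successes_in_pop=n_outcome,
        sample=len(exposed),
        observed=a + sum(
            1
            for tl in exposed
            if OUTCOME in tl.first_dx_day
            and tl.first_dx_day[OUTCOME] <= tl.first_dx_day[EXPOSURE]
        ),
    )
    cohort_rate = n_outcome / len(timelines)
    rate_pct, fold = rate_report(a, len(exposed), reference_rate=cohort_rate)

    result = {
        "table": {"a": a, "b": b, "c": c, "d": d},
        "relative_risk": rr.rr,
        "ci_95": [rr.ci_low, rr.ci_high],
        "p_value_rr": rr.p_value,
        "p_value_hypergeom": p_enrich,
        "exposed_rate_percent": rate_pct,
        "fold_vs_cohort_rate": fold,
    }
    (OUT / "validation_stats.json").write_text(json.dumps(result, indent=2))

    print(f"{OUTCOME} after {EXPOSURE}: {a} of {len(exposed)} exposed patients "
          f"({rate_pct}%)")
    print(f"RR = {rr.rr:.2f} [{rr.ci_low:.2f}-{rr.ci_high:.2f}, CI=0.95], "
          f"P = {rr.p_value:.2e}")
    print(f"hypergeometric enrichment P = {p_enrich:.2e}")
    print(f"{fold:.1f}-fold the cohort-wide rate of {100 * cohort_rate:.2f}%")


if __name__ == "__main__":
    main()
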