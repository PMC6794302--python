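#!/usr/bin/env python
"""Screen all disease pairs for relative association within one year.

Computes RA = C_ij / (I_i I_j / N) for every pair with both incidences
positive, tests each count with a one-sided binomial test and adjusts
with Benjamini–Hochberg; pairs with RA > 1 and FDR < 0.1 are selected.
Writes the full pair table and the selected subset.
"""

import argparse
from pathlib import Path

from trajmine.association import (
    compute_pair_statistics,
    pair_table,
    significant_pairs,
)
from trajmine.preprocess import MergePolicy, prepare_timelines
from trajmine.records import read_admissions

OUT = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--window-days", type=int, default=365)
    parser.add_argument("--fdr", type=float, default=0.1)
    args = parser.parse_args()

    records = read_admissions(OUT / "registry.csv")
    policy = MergePolicy(latest_edition=max(r.edition_id for r in records))
    timelines, _ = prepare_timelines(records, policy)

    stats = compute_pair_statistics(timelines, args.window_days)
    selected = significant_pairs(stats, ra_min=1.0, fdr=args.fdr)
    pair_table(stats).to_csv(OUT / "pair_stats.tsv", sep="\t", index=False)
    pair_table(selected).to_csv(OUT / "significant_pairs.tsv", sep="\t", index=False)

    print(f"{len(stats)} pairs tested, {len(selected)} significant "
          f"(RA > 1, FDR < {args.fdr})")
    for s in sorted(selected, key=lambda s: -s.RA):
        print(f"  {s.disease_i}-{s.disease_j}: RA={s.RA:.2f} C={s.C_ij} q={s.q_value:.2e}")


if __name__ == "__main__":
    main()
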