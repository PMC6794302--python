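#!/usr/bin/env python
"""Orient the significant pairs by temporal direction.

For each associated pair, per-patient ±1 order indicators (excluding
ties and gaps beyond one year) give the directionality score delta; a
two-sided sign test with Benjamini–Hochberg adjustment keeps pairs whose
direction is significant (FDR < 0.1), emitted source→target with the
forward inter-diagnosis interval statistics.
"""

import argparse
from pathlib import Path

from trajmine.association import compute_pair_statistics, significant_pairs
from trajmine.direction import directed_pair_table, directed_pairs
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
    selected = significant_pairs(
        compute_pair_statistics(timelines, args.window_days), fdr=args.fdr
    )
    oriented = directed_pairs(timelines, selected, args.window_days, args.fdr)
    directed_pair_table(oriented).to_csv(OUT / "directed_pairs.tsv", sep="\t", index=False)

    print(f"{len(oriented)} of {len(selected)} associated pairs have significant direction")
    for d in oriented:
        print(
            f"  {d.source}->{d.target}: delta={d.delta:.2f} "
            f"interval={d.interval_mean_days:.1f}±{d.interval_sd_days:.1f} d "
            f"(n={d.patient_count})"
        )


if __name__ == "__main__":
    main()
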