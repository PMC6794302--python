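#!/usr/bin/env python
"""Concatenate directed pairs into disease-trajectory DAGs.

Greedy construction: directed pairs sorted by patient count are chained
from every starting disease; an extension survives only if at least one
patient follows the whole sequence with every consecutive gap within one
year; followers dying in hospital at the end of a path feed the terminal
death node. Writes per-root DAG exports (JSON + DOT) and the path
summary table.
"""

import argparse
from pathlib import Path

from trajmine.association import compute_pair_statistics, significant_pairs
from trajmine.dag import DEATH, build_trajectories, export_dag, path_summary_table
from trajmine.direction import directed_pairs
from trajmine.preprocess import MergePolicy, prepare_timelines
from trajmine.records import read_admissions

OUT = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--window-days", type=int, default=365)
    args = parser.parse_args()

    records = read_admissions(OUT / "registry.csv")
    policy = MergePolicy(latest_edition=max(r.edition_id for r in records))
    timelines, _ = prepare_timelines(records, policy)
    selected = significant_pairs(compute_pair_statistics(timelines, args.window_days))
    oriented = directed_pairs(timelines, selected, args.window_days)
    dags = build_trajectories(oriented, timelines, args.window_days)

    path_summary_table(dags).to_csv(OUT / "paths.tsv", sep="\t", index=False)
    for dag in dags:
        (OUT / f"dag_{dag.root}.json").write_text(export_dag(dag, "json"))
        (OUT / f"dag_{dag.root}.dot").write_text(export_dag(dag, "dot"))

    print(f"{len(dags)} trajectory DAGs")
    for dag in dags:
        death = (
            f", {dag.graph.nodes[DEATH]['patient_count']} deaths"
            if DEATH in dag.graph
            else ""
        )
        print(f"  root {dag.root}: {dag.graph.number_of_nodes()} nodes{death}")
        for tp in dag.paths[:3]:
            print(f"    {'->'.join(tp.codes)}: {tp.n_followers} followers, "
                  f"{tp.n_deaths} deaths")


if __name__ == "__main__":
    main()
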