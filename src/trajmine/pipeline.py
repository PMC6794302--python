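"""End-to-end orchestration: simulate/load → preprocess → associate → orient → DAGs.

Every stage is a pure function of its inputs and all randomness flows
from the single configured seed, so a run is fully reproducible from its
manifest: identical config + seed → identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .association import (
    compute_pair_statistics,
    pair_table,
    significant_pairs,
)
from .dag import build_trajectories, export_dag, path_summary_table
from .direction import directed_pair_table, directed_pairs
from .errors import ConfigurationError, TrajmineError
from .preprocess import MergePolicy, prepare_timelines
from .records import read_admissions, write_admissions
from .simulate import SimulationConfig, generate_registry

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Exactly one of ``input_path`` (an admissions CSV) or ``simulation``
    must be given. Thresholds default to the standard screen:
    RA > 1 and FDR < 0.1 at both stages, one-year window.
    """

    output_dir: str | Path
    input_path: Optional[str | Path] = None
    simulation: Optional[SimulationConfig] = None
    merge_policy: Optional[MergePolicy] = None
    window_days: int = 365
    ra_min: float = 1.0
    fdr: float = 0.1
    export_formats: tuple[str, ...] = ("json",)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of input_path or simulation must be set"
            )
        if self.window_days <= 0 or self.ra_min < 0:
            raise ConfigurationError("thresholds must be positive")
        if not 0.0 < self.fdr < 1.0:
            raise ConfigurationError("fdr must lie in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write the output tables, return the run manifest.

    Outputs written under ``config.output_dir``:

    - ``registry.csv`` (simulated runs only) — the raw admissions
    - ``pair_stats.tsv`` — RA/p/q for every tested pair
    - ``directed_pairs.tsv`` — oriented significant pairs
    - ``paths.tsv`` — every complete trajectory path with follower counts
    - ``dag_<root>.<fmt>`` — per-root trajectory exports
    - ``filter_report.json`` — admissions dropped per non-disease category
    - ``manifest.json`` — config, seed, version, per-stage record counts
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            records = generate_registry(sim)
            write_admissions(records, outdir / "registry.csv")
            source = {"simulation": sim.to_dict()}
        else:
            records = read_admissions(config.input_path)
            source = {"input_path": str(config.input_path)}
    except TrajmineError as exc:
        raise TrajmineError(f"[stage: load] {exc}") from exc

    policy = config.merge_policy
    if policy is None and records:
        policy = MergePolicy(latest_edition=max(r.edition_id for r in records))

    try:
        timelines, filter_report = prepare_timelines(records, policy)
    except TrajmineError as exc:
        raise TrajmineError(f"[stage: preprocess] {exc}") from exc
    logger.info(
        "preprocess: %d admissions -> %d patients (%d dropped as non-disease)",
        len(records),
        len(timelines),
        sum(filter_report.values()),
    )

    try:
        stats = compute_pair_statistics(timelines, config.window_days)
        selected = significant_pairs(stats, config.ra_min, config.fdr)
    except TrajmineError as exc:
        raise TrajmineError(f"[stage: pair_association] {exc}") from exc
    logger.info("association: %d pairs tested, %d significant", len(stats), len(selected))

    try:
        oriented = directed_pairs(timelines, selected, config.window_days, config.fdr)
    except TrajmineError as exc:
        raise TrajmineError(f"[stage: temporal_direction] {exc}") from exc
    logger.info("direction: %d pairs oriented", len(oriented))

    try:
        dags = build_trajectories(oriented, timelines, config.window_days)
    except TrajmineError as exc:
        raise TrajmineError(f"[stage: dag_builder] {exc}") from exc
    logger.info("trajectories: %d DAGs built", len(dags))

    pair_table(stats).to_csv(outdir / "pair_stats.tsv", sep="\t", index=False)
    directed_pair_table(oriented).to_csv(
        outdir / "directed_pairs.tsv", sep="\t", index=False
    )
    path_summary_table(dags).to_csv(outdir / "paths.tsv", sep="\t", index=False)
    (outdir / "filter_report.json").write_text(json.dumps(filter_report, indent=2))
    for dag in dags:
        for fmt in config.export_formats:
            ext = {"json": "json", "graphml": "graphml", "dot": "dot"}[fmt]
            (outdir / f"dag_{dag.root}.{ext}").write_text(export_dag(dag, fmt))

    manifest = {
        "trajmine_version": __version__,
        "seed": config.seed,
        "window_days": config.window_days,
        "ra_min": config.ra_min,
        "fdr": config.fdr,
        "source": source,
        "merge_policy": None
        if policy is None
        else {
            "latest_edition": policy.latest_edition,
            "backfill_requires_death": policy.backfill_requires_death,
        },
        "counts": {
            "admissions": len(records),
            "admissions_dropped_nondisease": sum(filter_report.values()),
            "patients": len(timelines),
            "pairs_tested": len(stats),
            "pairs_significant": len(selected),
            "pairs_directed": len(oriented),
            "dags": len(dags),
            "paths": int(sum(len(d.paths) for d in dags)),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
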