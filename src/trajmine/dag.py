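"""Greedy construction of disease-trajectory DAGs from oriented pairs.

Directed pairs are sorted by patient count (descending; ties broken
lexically for determinism). For every distinct starting disease, paths are
grown greedily: from a path's terminal disease, each pair whose source is
that terminal and whose target is not already on the path is a candidate,
considered in the global sorted order; a candidate is attached only if at
least one patient follows the entire extended sequence — first-diagnosis
days strictly increasing, every consecutive gap within the window. All
viable extensions are attached (trajectories branch), each path tracked
separately. A path ends when no candidate has a follower.

Followers of a complete path who died in hospital on or after its final
diagnosis feed a distinguished terminal death node. Death is an optional
terminal: trajectories whose followers all survive are retained.

Node and edge annotations are patient sets accumulated over path
prefixes: a node's patients are all patients following some prefix ending
at that node, an edge's patients all patients following some prefix ending
with that edge. Edge counts therefore never exceed either endpoint's
count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import DEFAULT_WINDOW_DAYS
from .direction import DirectedPair
from .errors import AcyclicityError, TrajmineError
from .records import PatientTimeline

__all__ = [
    "DEATH",
    "TrajectoryPath",
    "TrajectoryDAG",
    "build_trajectories",
    "count_path_followers",
    "export_dag",
    "dag_from_json",
    "path_summary_table",
]

#: Identifier of the terminal death node.
DEATH = "DEATH"


@dataclass(frozen=True)
class TrajectoryPath:
    """A complete root-to-terminal code sequence with its follower counts."""

    codes: tuple[str, ...]
    n_followers: int
    n_deaths: int


@dataclass
class TrajectoryDAG:
    """A trajectory rooted at one starting diagnosis.

    ``graph`` is a :class:`networkx.DiGraph` whose disease nodes carry
    ``patient_count``, ``mean_age`` and ``death_count`` attributes and
    whose edges carry ``patient_count`` and ``interval_mean_days``; the
    death terminal (out-degree 0) is the node :data:`DEATH`.
    """

    root: str
    graph: nx.DiGraph
    paths: list[TrajectoryPath] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def count_path_followers(
    timelines: Sequence[PatientTimeline],
    path: Sequence[str],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> tuple[int, int]:
    """Count patients following the full ``path`` and those dying at its end.

    A follower's first-diagnosis days are strictly increasing along the
    path with every consecutive gap at most ``window_days``; a death is a
    follower whose in-hospital death day is on or after the final
    diagnosis day.
    """
    if len(path) < 2:
        raise TrajmineError("a trajectory path needs at least two diseases")
    n_followers = 0
    n_deaths = 0
    for tl in timelines:
        days = tl.first_dx_day
        prev = None
        for code in path:
            day = days.get(code)
            if day is None or (prev is not None and not 0 < day - prev <= window_days):
                break
            prev = day
        else:
            n_followers += 1
            if tl.death_day is not None and tl.death_day >= prev:
                n_deaths += 1
    return n_followers, n_deaths


def _sorted_pairs(pairs: Iterable[DirectedPair]) -> list[DirectedPair]:
    pair_list = sorted(
        pairs, key=lambda d: (-d.patient_count, d.source, d.target)
    )
    seen = {(d.source, d.target) for d in pair_list}
    for d in pair_list:
        if (d.target, d.source) in seen:
            raise AcyclicityError(
                f"both orientations of pair ({d.source}, {d.target}) supplied; "
                "directionality must be antisymmetric"
            )
    return pair_list


def build_trajectories(
    pairs: Sequence[DirectedPair],
    timelines: Sequence[PatientTimeline],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> list[TrajectoryDAG]:
    """Build one trajectory DAG per starting disease with a viable first step.

    Roots are the distinct source diseases of the sorted pair list; a DAG
    is emitted only if at least one first step has a follower.
    """
    pair_list = _sorted_pairs(pairs)
    by_source: dict[str, list[DirectedPair]] = {}
    for d in pair_list:
        by_source.setdefault(d.source, []).append(d)

    # first-diagnosis day per code per patient, for incremental follower sets
    dags: list[TrajectoryDAG] = []
    roots = sorted(by_source, key=lambda r: (-by_source[r][0].patient_count, r))
    for root in roots:
        dag = _build_single(root, by_source, timelines, window_days)
        if dag is not None:
            dags.append(dag)
    return dags


def _build_single(
    root: str,
    by_source: Mapping[str, list[DirectedPair]],
    timelines: Sequence[PatientTimeline],
    window_days: int,
) -> TrajectoryDAG | None:
    root_followers = [p for p, tl in enumerate(timelines) if root in tl.first_dx_day]
    if not root_followers:
        return None

    node_sets: dict[str, set[int]] = {root: set(root_followers)}
    edge_sets: dict[tuple[str, str], set[int]] = {}
    completed: list[TrajectoryPath] = []
    death_edges: dict[str, set[int]] = {}

    # depth-first over path prefixes, follower sets filtered incrementally
    stack: list[tuple[tuple[str, ...], list[int]]] = [((root,), root_followers)]
    while stack:
        path, followers = stack.pop()
        terminal = path[-1]
        extended = False
        for cand in by_source.get(terminal, []):
            nxt = cand.target
            if nxt in path:
                continue
            survivors = []
            for p in followers:
                tl = timelines[p]
                day = tl.first_dx_day.get(nxt)
                if day is not None and 0 < day - tl.first_dx_day[terminal] <= window_days:
                    survivors.append(p)
            if not survivors:
                continue
            extended = True
            new_path = path + (nxt,)
            node_sets.setdefault(nxt, set()).update(survivors)
            edge_sets.setdefault((terminal, nxt), set()).update(survivors)
            stack.append((new_path, survivors))
        if not extended and len(path) >= 2:
            last = path[-1]
            deaths = {
                p
                for p in followers
                if timelines[p].death_day is not None
                and timelines[p].death_day >= timelines[p].first_dx_day[last]
            }
            completed.append(
                TrajectoryPath(
                    codes=path, n_followers=len(followers), n_deaths=len(deaths)
                )
            )
            if deaths:
                death_edges.setdefault(last, set()).update(deaths)

    if not completed:
        return None

    graph = nx.DiGraph()
    for code, pset in node_sets.items():
        ages = [timelines[p].ages.get(code, np.nan) for p in pset]
        deaths = sum(
            1
            for p in pset
            if timelines[p].death_day is not None
            and timelines[p].death_day >= timelines[p].first_dx_day[code]
        )
        graph.add_node(
            code,
            patient_count=len(pset),
            mean_age=float(np.nanmean(ages)) if pset else float("nan"),
            death_count=deaths,
            is_death=False,
            shape="circle",
        )
    for (s, t), pset in edge_sets.items():
        gaps = [timelines[p].first_dx_day[t] - timelines[p].first_dx_day[s] for p in pset]
        graph.add_edge(
            s, t, patient_count=len(pset), interval_mean_days=float(np.mean(gaps))
        )
    if death_edges:
        all_deaths = set().union(*death_edges.values())
        graph.add_node(
            DEATH,
            patient_count=len(all_deaths),
            mean_age=float("nan"),
            death_count=len(all_deaths),
            is_death=True,
            shape="square",
        )
        for last, pset in death_edges.items():
            graph.add_edge(
                last, DEATH, patient_count=len(pset), interval_mean_days=float("nan")
            )

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise AcyclicityError(f"trajectory graph of root {root!r} has a cycle: {cycle}")

    completed.sort(key=lambda tp: (-tp.n_followers, tp.codes))
    return TrajectoryDAG(root=root, graph=graph, paths=completed)


def export_dag(dag: TrajectoryDAG, format: str = "json") -> str:
    """Serialize a trajectory DAG as ``json``, ``graphml`` or ``dot`` text.

    JSON round-trips losslessly via :func:`dag_from_json`; GraphML and DOT
    carry the node/edge annotations as attributes (the death node keeps a
    distinct ``shape`` attribute for rendering).
    """
    if format == "json":
        payload = {
            "root": dag.root,
            "nodes": [
                {"id": n, **{k: _jsonable(v) for k, v in attrs.items()}}
                for n, attrs in sorted(dag.graph.nodes(data=True))
            ],
            "edges": [
                {"source": s, "target": t, **{k: _jsonable(v) for k, v in attrs.items()}}
                for s, t, attrs in sorted(dag.graph.edges(data=True))
            ],
            "paths": [
                {
                    "codes": list(tp.codes),
                    "n_followers": tp.n_followers,
                    "n_deaths": tp.n_deaths,
                }
                for tp in dag.paths
            ],
        }
        return json.dumps(payload, indent=2)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(_nan_free(dag.graph)))
    if format == "dot":
        return _to_dot(dag)
    raise TrajmineError(f"unknown export format {format!r}")


def dag_from_json(text: str) -> TrajectoryDAG:
    """Reconstruct a :class:`TrajectoryDAG` from its JSON export."""
    payload = json.loads(text)
    graph = nx.DiGraph()
    for node in payload["nodes"]:
        attrs = dict(node)
        graph.add_node(attrs.pop("id"), **_nan_in(attrs))
    for edge in payload["edges"]:
        attrs = dict(edge)
        graph.add_edge(attrs.pop("source"), attrs.pop("target"), **_nan_in(attrs))
    paths = [
        TrajectoryPath(tuple(p["codes"]), p["n_followers"], p["n_deaths"])
        for p in payload["paths"]
    ]
    return TrajectoryDAG(root=payload["root"], graph=graph, paths=paths)


def path_summary_table(dags: Sequence[TrajectoryDAG]) -> pd.DataFrame:
    """All complete paths of all DAGs: sequence, followers, deaths."""
    rows = [
        {
            "root": dag.root,
            "path": "->".join(tp.codes),
            "length": len(tp.codes),
            "n_followers": tp.n_followers,
            "n_deaths": tp.n_deaths,
        }
        for dag in dags
        for tp in dag.paths
    ]
    return pd.DataFrame(
        rows, columns=["root", "path", "length", "n_followers", "n_deaths"]
    )


def _jsonable(v):
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def _nan_in(attrs: dict) -> dict:
    return {k: (float("nan") if v is None else v) for k, v in attrs.items()}


def _nan_free(graph: nx.DiGraph) -> nx.DiGraph:
    # GraphML cannot carry NaN portably; encode as -1 sentinel
    g = graph.copy()
    for _, attrs in g.nodes(data=True):
        for k, v in attrs.items():
            if isinstance(v, float) and np.isnan(v):
                attrs[k] = -1.0
    for _, _, attrs in g.edges(data=True):
        for k, v in attrs.items():
            if isinstance(v, float) and np.isnan(v):
                attrs[k] = -1.0
    return g


def _to_dot(dag: TrajectoryDAG) -> str:
    lines = [f'digraph "{dag.root}" {{']
    for n, attrs in sorted(dag.graph.nodes(data=True)):
        shape = "box" if attrs.get("is_death") else "ellipse"
        label = f"{n}\\n{attrs.get('patient_count', 0)} patients"
        lines.append(f'  "{n}" [shape={shape}, label="{label}"];')
    for s, t, attrs in sorted(dag.graph.edges(data=True)):
        lines.append(
            f'  "{s}" -> "{t}" [label="{attrs.get("patient_count", 0)}"];'
        )
    lines.append("}")
    return "\n".join(lines)
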