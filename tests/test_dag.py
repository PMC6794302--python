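"""Greedy trajectory construction, follower counting, exports."""

import networkx as nx
import numpy as np
import pytest

from trajmine.dag import (
    DEATH,
    build_trajectories,
    count_path_followers,
    dag_from_json,
    export_dag,
)
from trajmine.direction import DirectedPair
from trajmine.errors import AcyclicityError, TrajmineError

from conftest import make_timeline


def dp(source, target, patient_count):
    return DirectedPair(
        source=source,
        target=target,
        n_ordered_patients=patient_count,
        n_forward=patient_count,
        delta=1.0,
        p_value=0.001,
        q_value=0.001,
        interval_mean_days=100.0,
        interval_sd_days=50.0,
        patient_count=patient_count,
    )


def followers_oracle(timelines, path, window=365):
    """Independent per-patient reimplementation of follower counting."""
    n_f = n_d = 0
    for tl in timelines:
        days = [tl.first_dx_day.get(c) for c in path]
        if any(d is None for d in days):
            continue
        if all(0 < b - a <= window for a, b in zip(days, days[1:])):
            n_f += 1
            if tl.death_day is not None and tl.death_day >= days[-1]:
                n_d += 1
    return n_f, n_d


@pytest.fixture
def chain_timelines():
    """10 patients follow A→B→C fully; extra patients pad the pair counts."""
    tls = [
        make_timeline(f"full{i}", {"A": 0, "B": 100, "C": 300},
                      death_day=300 if i < 4 else None)
        for i in range(10)
    ]
    tls += [make_timeline(f"ab{i}", {"A": 0, "B": 200}) for i in range(90)]
    tls += [make_timeline(f"bc{i}", {"B": 0, "C": 150}) for i in range(40)]
    return tls


class TestCountPathFollowers:
    def test_follower(self):
        tls = [make_timeline("p", {"A": 0, "B": 100, "C": 300})]
        assert count_path_followers(tls, ["A", "B", "C"]) == (1, 0)

    def test_gap_too_large(self):
        tls = [make_timeline("p", {"A": 0, "B": 500})]
        assert count_path_followers(tls, ["A", "B"]) == (0, 0)

    def test_death_counted(self):
        tls = [make_timeline("p", {"A": 0, "B": 100}, death_day=100)]
        assert count_path_followers(tls, ["A", "B"]) == (1, 1)

    def test_short_path_rejected(self):
        with pytest.raises(TrajmineError):
            count_path_followers([], ["A"])

    def test_monotone_under_extension(self, chain_timelines):
        n_ab, _ = count_path_followers(chain_timelines, ["A", "B"])
        n_abc, _ = count_path_followers(chain_timelines, ["A", "B", "C"])
        assert n_abc <= n_ab


class TestBuildTrajectories:
    def test_chain(self, chain_timelines):
        dags = build_trajectories([dp("A", "B", 100), dp("B", "C", 50)], chain_timelines)
        by_root = {d.root: d for d in dags}
        assert set(by_root) == {"A", "B"}
        dag_a = by_root["A"]
        [path] = dag_a.paths
        assert path.codes == ("A", "B", "C")
        assert path.n_followers == 10
        assert path.n_deaths == 4
        assert dag_a.graph.has_edge("C", DEATH)

    def test_minimal_single_pair(self):
        tls = [make_timeline("p", {"A": 0, "B": 100})]
        [dag] = build_trajectories([dp("A", "B", 1)], tls)
        assert list(dag.graph.edges) == [("A", "B")]
        [path] = dag.paths
        assert path.codes == ("A", "B") and path.n_followers == 1

    def test_forced_cycle_raises(self, chain_timelines):
        with pytest.raises(AcyclicityError):
            build_trajectories([dp("A", "B", 10), dp("B", "A", 5)], chain_timelines)

    def test_all_dags_acyclic_and_counts_consistent(self, chain_timelines):
        dags = build_trajectories([dp("A", "B", 100), dp("B", "C", 50)], chain_timelines)
        for dag in dags:
            assert nx.is_directed_acyclic_graph(dag.graph)
            assert dag.graph.out_degree(DEATH) == 0 if DEATH in dag.graph else True
            for s, t, attrs in dag.graph.edges(data=True):
                assert (
                    attrs["patient_count"]
                    <= min(
                        dag.graph.nodes[s]["patient_count"],
                        dag.graph.nodes[t]["patient_count"],
                    )
                )

    def test_no_follower_no_dag(self):
        tls = [make_timeline("p", {"A": 0, "B": 500})]  # gap beyond window
        assert build_trajectories([dp("A", "B", 1)], tls) == []

    def test_greedy_counts_match_oracle(self, chain_timelines):
        dags = build_trajectories([dp("A", "B", 100), dp("B", "C", 50)], chain_timelines)
        for dag in dags:
            for path in dag.paths:
                assert (path.n_followers, path.n_deaths) == followers_oracle(
                    chain_timelines, path.codes
                )


class TestExport:
    @pytest.fixture
    def dag(self, chain_timelines):
        dags = build_trajectories([dp("A", "B", 100), dp("B", "C", 50)], chain_timelines)
        return next(d for d in dags if d.root == "A")

    def test_json_roundtrip(self, dag):
        back = dag_from_json(export_dag(dag, "json"))
        assert back.root == dag.root
        assert back.paths == dag.paths
        assert nx.utils.graphs_equal(back.graph, dag.graph) or (
            set(back.graph.nodes) == set(dag.graph.nodes)
            and set(back.graph.edges) == set(dag.graph.edges)
        )

    def test_dot_output(self, dag):
        dot = export_dag(dag, "dot")
        assert dot.startswith("digraph")
        assert '"A" -> "B"' in dot
        assert "shape=box" in dot  # the death terminal is drawn distinctly

    def test_graphml_parses(self, dag):
        g = nx.parse_graphml(export_dag(dag, "graphml"))
        assert set(g.edges) == {(str(s), str(t)) for s, t in dag.graph.edges}

    def test_unknown_format(self, dag):
        with pytest.raises(TrajmineError):
            export_dag(dag, "pdf")
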