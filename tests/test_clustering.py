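"""Markov clustering and the temporal mining / redundancy-filter chain."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tepinkit import (
    ComplexCatalog,
    MarkovClustering,
    MCLParams,
    PredictedComplexSet,
    Snapshot,
    TemporalComplexMiner,
    TemporalNetwork,
    filter_redundant,
    mcl_cluster,
    mine_temporal_complexes,
)


def dense_mcl_oracle(A, inflation=2.0, self_loops=1.0, iterations=60):
    """Literal dense transcription of the expand/inflate iteration, no
    pruning: the independent reference the sparse implementation must match."""
    n = A.shape[0]
    M = A + self_loops * np.eye(n)
    M = M / M.sum(axis=0)
    for _ in range(iterations):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
    clusters = set()
    for i in range(n):
        if M[i, i] > 1e-6:
            clusters.add(frozenset(np.flatnonzero(M[i] > 1e-6)))
    return clusters


def snapshot_of(edges, nodes=(), t=1):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        g.add_edge(*e[:2], **({"weight": e[2]} if len(e) == 3 else {}))
    return Snapshot(t, g)


def test_two_disjoint_triangles_recovered():
    edges = [("A", "B"), ("B", "C"), ("A", "C"),
             ("X", "Y"), ("Y", "Z"), ("X", "Z")]
    for inflation in (1.5, 2.0, 2.5):
        clusters = mcl_cluster(
            snapshot_of(edges), MCLParams(inflation=inflation)
        )
        assert set(clusters) == {
            frozenset({"A", "B", "C"}), frozenset({"X", "Y", "Z"})
        }


def test_single_edge_and_empty_snapshot():
    assert mcl_cluster(snapshot_of([("A", "B")])) == [frozenset({"A", "B"})]
    assert mcl_cluster(snapshot_of([])) == []


def test_mcl_matches_dense_oracle_on_k5_plus_pendant():
    g = nx.complete_graph(5)
    g.add_edge(4, 5)
    A = nx.to_numpy_array(g, nodelist=range(6))
    expected = dense_mcl_oracle(A)
    mcl = MarkovClustering(inflation=2.0).fit(g)
    got = {
        frozenset(mcl.nodes_.index(n) for n in c) for c in mcl.clusters_
    }
    assert got == expected


def test_mcl_matches_dense_oracle_on_random_graphs(rng):
    for trial in range(5):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
        A = nx.to_numpy_array(g, nodelist=range(12))
        expected = dense_mcl_oracle(A)
        mcl = MarkovClustering().fit(g)
        got = {
            frozenset(mcl.nodes_.index(n) for n in c) for c in mcl.clusters_
        }
        assert got == expected


def test_column_stochasticity_preserved():
    """Columns sum to 1 after every inflation step."""
    from scipy import sparse

    from tepinkit.clustering import _column_normalize, _prune

    rng = np.random.default_rng(7)
    A = sparse.random(30, 30, density=0.2, random_state=7, format="csc")
    A = abs(A + A.T)
    M = _column_normalize((A + sparse.identity(30)).tocsc())
    for _ in range(10):
        M = _column_normalize(_prune((M @ M).tocsc().power(2.0), 1e-5))
        sums = np.asarray(M.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-9)


def test_no_cross_component_merging(rng):
    """Flow cannot cross disconnected components."""
    g = nx.disjoint_union(
        nx.gnp_random_graph(8, 0.5, seed=1), nx.gnp_random_graph(7, 0.5, seed=2)
    )
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = ci
    for cluster in MarkovClustering().fit(g).clusters_:
        assert len({comp_of[n] for n in cluster}) == 1


def test_every_node_clustered_and_weights_respected():
    # two heavy triangles joined by a near-zero bridge: the weak edge
    # cannot hold the components together
    edges = [("A", "B", 5.0), ("B", "C", 5.0), ("A", "C", 5.0),
             ("C", "D", 0.05),
             ("D", "E", 5.0), ("E", "F", 5.0), ("D", "F", 5.0)]
    clusters = mcl_cluster(snapshot_of(edges))
    assert set().union(*clusters) == {"A", "B", "C", "D", "E", "F"}
    assert frozenset({"A", "B", "C"}) in clusters
    assert frozenset({"D", "E", "F"}) in clusters


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        MarkovClustering().fit(snapshot_of([("A", "B", -1.0)]))


def pcs(member_sets):
    return PredictedComplexSet(
        ComplexCatalog([(f"P{i}", frozenset(m))
                        for i, m in enumerate(member_sets)]),
        {f"P{i}": frozenset({1}) for i in range(len(member_sets))},
    )


def test_filter_redundant_examples():
    # exact duplicates collapse at threshold 1.0
    out = filter_redundant(pcs([{"A", "B", "C"}, {"A", "B", "C"}]), 1.0)
    assert [m for _, m in out.catalog] == [frozenset({"A", "B", "C"})]

    # OS({ABCD},{ABC}) = 9/12 = 0.75: both survive at 0.8, smaller dies at 0.7
    pair = [{"A", "B", "C", "D"}, {"A", "B", "C"}]
    assert len(filter_redundant(pcs(pair), 0.8)) == 2
    kept = filter_redundant(pcs(pair), 0.7)
    assert [m for _, m in kept.catalog] == [frozenset({"A", "B", "C", "D"})]


def test_filter_redundant_properties(rng):
    member_sets = [
        frozenset(f"p{i}" for i in rng.choice(20, size=rng.integers(2, 8),
                                              replace=False))
        for _ in range(30)
    ]
    predicted = pcs(member_sets)
    once = filter_redundant(predicted, 0.6)
    twice = filter_redundant(once, 0.6)
    assert once.catalog == twice.catalog  # idempotent
    assert len(once) <= len(predicted)    # monotone shrinkage
    largest = max(len(m) for m in predicted.catalog.member_sets())
    assert max(len(m) for m in once.catalog.member_sets()) == largest


def test_mine_merges_and_removes_singletons():
    tri = [("A", "B"), ("B", "C"), ("A", "C")]
    net = TemporalNetwork([
        snapshot_of(tri, t=1),
        snapshot_of(tri, t=2),
        snapshot_of([], nodes={"Q"}, t=3),  # isolated node -> singleton, wiped
    ])
    predicted = mine_temporal_complexes(net, similarity_threshold=1.0)
    assert predicted.catalog.member_sets() == [frozenset({"A", "B", "C"})]
    label = predicted.catalog.complexes[0][0]
    assert predicted.provenance[label] == frozenset({1, 2})


def test_mine_on_single_snapshot_equals_direct_clustering():
    edges = [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"),
             ("X", "Z"), ("C", "X")]
    snap = snapshot_of(edges)
    direct = {c for c in mcl_cluster(snap) if len(c) >= 2}
    mined = mine_temporal_complexes(
        TemporalNetwork([snap]), similarity_threshold=1.0
    )
    assert set(mined.catalog.member_sets()) == direct


def test_empty_network_yields_empty_set():
    net = TemporalNetwork([snapshot_of([], t=1), snapshot_of([], t=2)])
    assert len(mine_temporal_complexes(net)) == 0


def test_pluggable_clusterer():
    calls = []

    def fake(snap):
        calls.append(snap.timepoint)
        return [frozenset({"A", "B"})]

    net = TemporalNetwork([snapshot_of([("A", "B")], t=1),
                           snapshot_of([("A", "B")], t=2)])
    predicted = mine_temporal_complexes(net, fake, 1.0)
    assert calls == [1, 2]
    assert predicted.catalog.member_sets() == [frozenset({"A", "B"})]


def test_miner_estimator_facade():
    net = TemporalNetwork([
        snapshot_of([("A", "B"), ("B", "C"), ("A", "C")], t=1)
    ])
    miner = TemporalComplexMiner(inflation=2.0)
    assert miner.fit_predict(net) == [frozenset({"A", "B", "C"})]
    assert miner.get_params()["similarity_threshold"] == 1.0
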