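"""Assembly of the time-evolving network: one induced subgraph of the static
PIN per time point, restricted to the proteins active there.

Isolated active proteins (no surviving interaction at that time point) are
kept as snapshot nodes — the construction reserves the active proteins and
then their interactions — but carry no edges, so clustering ignores them.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .datatypes import ActivitySchedule, Snapshot, StaticPIN, TemporalNetwork


def build_tepin(pin: StaticPIN, schedule: ActivitySchedule) -> TemporalNetwork:
    """Induce the static PIN on each per-time-point active protein set."""
    base = pin.to_networkx()
    snapshots = []
    for t, active in enumerate(schedule.active_sets(), start=1):
        nodes = active & pin.proteins
        snapshots.append(Snapshot(t, nx.Graph(base.subgraph(nodes))))
    return TemporalNetwork(snapshots)


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Undirected density 2E / (N(N-1)); defined as 0 for N <= 1."""
    if n_nodes <= 1:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def network_properties(net: TemporalNetwork | StaticPIN) -> pd.DataFrame:
    """Per-snapshot node/edge counts and densities, plus an ``average`` row.

    The average density is the arithmetic mean of the per-snapshot densities,
    not the density of the averaged counts — small dense snapshots therefore
    pull the average density up even when mean counts suggest otherwise.
    For a static PIN the table has a single row.
    """
    if isinstance(net, StaticPIN):
        rows = [("static", net.n_proteins, net.n_edges,
                 graph_density(net.n_proteins, net.n_edges))]
    else:
        rows = [
            (snap.timepoint, snap.n_nodes, snap.n_edges,
             graph_density(snap.n_nodes, snap.n_edges))
            for snap in net
        ]
    df = pd.DataFrame(rows, columns=["timepoint", "nodes", "edges", "density"])
    avg = pd.DataFrame(
        [("average", df["nodes"].mean(), df["edges"].mean(),
          df["density"].mean())],
        columns=df.columns,
    )
    return pd.concat([df, avg], ignore_index=True)
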