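"""Core containers shared by every pipeline stage.

Graphs are kept as :class:`networkx.Graph` objects wrapped in thin dataclasses
that enforce the invariants the downstream maths relies on (no self-loops, no
duplicate edges, unique gene IDs, complex size >= 2).  Edges are always
addressed through their canonical sorted-tuple form so that an unordered pair
has exactly one dictionary key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

Edge = tuple[str, str]


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) as a sorted tuple."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class StaticPIN:
    """Undirected static protein interaction network.

    Invariants: no self-loops, unordered-unique edges, every edge endpoint is
    a member of ``proteins``.  Proteins appearing only in self-loops of the
    source file are never added (the network counts interacting proteins).
    """

    proteins: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != canonical_edge(u, v):
                raise ValueError(f"edge {(u, v)!r} not in canonical order")
            if u not in self.proteins or v not in self.proteins:
                raise ValueError(f"edge {(u, v)!r} has endpoint outside protein set")

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "StaticPIN":
        """Build a PIN from raw pairs, dropping self-loops and duplicates."""
        edges = {canonical_edge(u, v) for u, v in pairs if u != v}
        proteins = {p for e in edges for p in e}
        return cls(frozenset(proteins), frozenset(edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_edge(u, v) in self.edges

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class ExpressionMatrix:
    """Gene-by-time-point expression matrix with an ordered time axis.

    Time points are indexed 1..n throughout the package, mirroring the usual
    presentation of time-course series.  Backed by a float pandas DataFrame
    whose index holds the gene IDs.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if data.shape[1] < 1:
            raise ValueError("expression matrix needs at least one time point")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        self.data = data.astype(float)

    @classmethod
    def from_array(
        cls,
        genes: Sequence[str],
        values: np.ndarray,
        timepoint_labels: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(genes):
            raise ValueError("values must be a (n_genes, n_timepoints) array")
        cols = (
            list(timepoint_labels)
            if timepoint_labels is not None
            else [f"T{t}" for t in range(1, values.shape[1] + 1)]
        )
        return cls(pd.DataFrame(values, index=list(genes), columns=cols))

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.genes == other.genes and np.allclose(
            self.values, other.values, rtol=0, atol=1e-12
        )


@dataclass
class ComplexCatalog:
    """Ordered list of labelled protein complexes (member sets of size >= 2)."""

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.complexes]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate complex labels")
        for label, members in self.complexes:
            if len(members) < 2:
                raise ValueError(f"complex {label!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.complexes]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexCatalog):
            return NotImplemented
        return self.complexes == other.complexes


@dataclass(frozen=True)
class AnnotationMap:
    """Functional annotation: term ID -> annotated protein set, plus the
    genome size N used as the population in the hypergeometric test."""

    terms: Mapping[str, frozenset[str]]
    genome_size: int

    def __post_init__(self) -> None:
        universe: set[str] = set()
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} annotates no proteins")
            universe |= set(members)
        if self.genome_size < len(universe):
            raise ValueError("genome_size smaller than annotated universe")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-gene activity summary: mean, sample SD, threshold = mean + SD, and
    the 1-based time points where expression strictly exceeds the threshold."""

    gene: str
    mean: float
    sd: float
    threshold: float
    active_timepoints: frozenset[int]


@dataclass
class ActivitySchedule:
    """ActivityProfile per gene plus the shared number of time points."""

    profiles: dict[str, ActivityProfile]
    n_timepoints: int

    def active_set(self, timepoint: int) -> set[str]:
        """Genes active at a 1-based time point."""
        if not 1 <= timepoint <= self.n_timepoints:
            raise ValueError(f"timepoint {timepoint} outside 1..{self.n_timepoints}")
        return {
            g for g, p in self.profiles.items() if timepoint in p.active_timepoints
        }

    def active_sets(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_timepoints)]
        for g, p in self.profiles.items():
            for t in p.active_timepoints:
                out[t - 1].add(g)
        return out


@dataclass
class Snapshot:
    """One time-point subgraph of the static PIN, optionally edge-weighted."""

    timepoint: int
    graph: nx.Graph

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    @property
    def weights(self) -> dict[Edge, float]:
        return {
            canonical_edge(u, v): d["weight"]
            for u, v, d in self.graph.edges(data=True)
            if "weight" in d
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class TemporalNetwork:
    """Ordered sequence of snapshots, time points exactly 1..n."""

    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        for i, snap in enumerate(self.snapshots, start=1):
            if snap.timepoint != i:
                raise ValueError("snapshot time points must be 1..n in order")

    @property
    def n_timepoints(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __getitem__(self, idx: int) -> Snapshot:
        return self.snapshots[idx]


@dataclass
class PredictedComplexSet:
    """Predicted complexes with provenance: which snapshots produced each
    identical member set."""

    catalog: ComplexCatalog
    provenance: dict[str, frozenset[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.catalog)


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering parameters (community-standard defaults)."""

    inflation: float = 2.0
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must exceed 1")
        if self.self_loop_weight < 0 or self.prune_threshold < 0:
            raise ValueError("self_loop_weight and prune_threshold must be >= 0")
        if self.max_iterations < 1 or not self.convergence_tol > 0:
            raise ValueError("max_iterations >= 1 and convergence_tol > 0 required")


@dataclass(frozen=True)
class MatchResult:
    """Predicted-vs-known matching counts at a fixed overlap-score threshold.

    Conservation: TP + FP = #predicted and MKC + FN = #known; a predicted
    complex matching several known complexes still counts once in TP, and a
    known complex matched by several predictions counts once in MKC.
    """

    os_threshold: float
    n_predicted: int
    n_known: int
    TP: int
    FP: int
    MKC: int
    FN: int
    perfect: int

    def __post_init__(self) -> None:
        if self.TP + self.FP != self.n_predicted:
            raise ValueError("TP + FP must equal the number of predicted complexes")
        if self.MKC + self.FN != self.n_known:
            raise ValueError("MKC + FN must equal the number of known complexes")
        if self.perfect > self.MKC:
            raise ValueError("perfect matches cannot exceed MKC")


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy summary derived from a MatchResult: sensitivity Sn,
    specificity Sp and their harmonic mean (F-measure)."""

    match: MatchResult
    Sn: float
    Sp: float
    F: float
    average_predicted_size: float = float("nan")
    matched_known_percentage: float = float("nan")


DetectorFn = Callable[[np.ndarray], frozenset[int]]
"""Pluggable activity rule: expression row -> 1-based active time points."""
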