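"""Temporal complex mining.

A clustering algorithm runs independently on each snapshot of the temporal
network; the n per-snapshot result groups are merged into one set, single-
protein clusters are wiped out, and a size-ordered redundancy filter removes
near-duplicate complexes (similarity = overlapping score).

The bundled clusterer is Markov clustering (MCL): the weighted adjacency
matrix, with self-loops added, is made column-stochastic and then iterated
through expansion (matrix squaring, spreading flow) and inflation
(entrywise power followed by renormalisation, sharpening flow) until the
matrix converges; clusters are read off the attractor rows.  Flow cannot
cross between disconnected components, so MCL never merges them.  Any other
callable mapping a snapshot to an iterable of protein sets can be plugged
in instead (e.g. wrappers around external complex-detection tools).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy import sparse

from .datatypes import (
    ComplexCatalog,
    MCLParams,
    PredictedComplexSet,
    Snapshot,
    TemporalNetwork,
)
from .evaluation import overlap_score

ClustererFn = Callable[[Snapshot], Iterable[frozenset[str]]]


def _column_normalize(M: sparse.csc_matrix) -> sparse.csc_matrix:
    col_sums = np.asarray(M.sum(axis=0)).ravel()
    col_sums[col_sums == 0.0] = 1.0
    return (M @ sparse.diags(1.0 / col_sums)).tocsc()


def _prune(M: sparse.csc_matrix, threshold: float) -> sparse.csc_matrix:
    """Zero entries below threshold, but never empty a non-zero column:
    each column's maximum survives so stochasticity can be restored."""
    if threshold <= 0.0 or M.nnz == 0:
        return M
    M = M.tocsc()
    keep = M.data >= threshold
    # column maxima must survive pruning
    for j in range(M.shape[1]):
        lo, hi = M.indptr[j], M.indptr[j + 1]
        if lo == hi:
            continue
        keep[lo + int(np.argmax(M.data[lo:hi]))] = True
    M.data[~keep] = 0.0
    M.eliminate_zeros()
    return M


class MarkovClustering:
    """Markov clustering with the scikit-learn clusterer protocol.

    Parameters mirror :class:`~tepinkit.datatypes.MCLParams`.  ``fit``
    accepts a networkx graph, a :class:`Snapshot`, or a symmetric
    non-negative adjacency matrix (dense or sparse).

    Fitted attributes
    -----------------
    nodes_ : list
        Node identifiers in matrix order (sorted for graphs).
    clusters_ : list of frozenset
        Every node belongs to at least one cluster; overlapping attractor
        supports yield overlapping clusters.
    labels_ : ndarray of int
        Index of the first cluster containing each node (scikit-learn
        compatibility view of the possibly-overlapping ``clusters_``).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        inflation: float = 2.0,
        self_loop_weight: float = 1.0,
        prune_threshold: float = 1e-5,
        max_iterations: int = 100,
        convergence_tol: float = 1e-6,
    ) -> None:
        self.inflation = inflation
        self.self_loop_weight = self_loop_weight
        self.prune_threshold = prune_threshold
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "inflation": self.inflation,
            "self_loop_weight": self.self_loop_weight,
            "prune_threshold": self.prune_threshold,
            "max_iterations": self.max_iterations,
            "convergence_tol": self.convergence_tol,
        }

    def set_params(self, **params) -> "MarkovClustering":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def params(self) -> MCLParams:
        return MCLParams(**self.get_params())

    def _adjacency(self, X) -> tuple[sparse.csc_matrix, list]:
        import networkx as nx

        if isinstance(X, Snapshot):
            X = X.graph
        if isinstance(X, nx.Graph):
            nodes = sorted(X.nodes)
            if not nodes:
                return sparse.csc_matrix((0, 0)), []
            A = nx.to_scipy_sparse_array(
                X, nodelist=nodes, weight="weight", format="csc"
            )
            return sparse.csc_matrix(A), nodes
        A = sparse.csc_matrix(X, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        return A, list(range(A.shape[0]))

    def fit(self, X, y=None) -> "MarkovClustering":
        self.params  # validates ranges
        A, nodes = self._adjacency(X)
        self.nodes_ = nodes
        n = A.shape[0]
        if n == 0:
            self.clusters_ = []
            self.labels_ = np.empty(0, dtype=int)
            self.n_iter_ = 0
            self.converged_ = True
            return self
        if A.nnz and A.data.min() < 0:
            raise ValueError("adjacency weights must be non-negative")
        M = (A + self.self_loop_weight * sparse.identity(n, format="csc")).tocsc()
        M = _column_normalize(M)
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iterations + 1):
            expanded = (M @ M).tocsc()
            inflated = expanded.power(self.inflation)
            inflated = _prune(inflated, self.prune_threshold)
            inflated = _column_normalize(inflated)
            change = abs(inflated - M).max() if (inflated - M).nnz else 0.0
            M = inflated
            if change < self.convergence_tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        self.clusters_ = self._read_clusters(M, nodes)
        labels = np.full(n, -1, dtype=int)
        index = {node: i for i, node in enumerate(nodes)}
        for ci, cluster in enumerate(self.clusters_):
            for node in cluster:
                if labels[index[node]] == -1:
                    labels[index[node]] = ci
        self.labels_ = labels
        return self

    @staticmethod
    def _read_clusters(M: sparse.csc_matrix, nodes: list) -> list[frozenset]:
        csr = M.tocsr()
        attractors = np.flatnonzero(csr.diagonal() > 1e-6)
        raw: list[frozenset] = []
        for i in attractors:
            support = csr.indices[csr.indptr[i]:csr.indptr[i + 1]]
            raw.append(frozenset(nodes[j] for j in support))
        clusters: list[frozenset] = []
        seen: set[frozenset] = set()
        for c in raw:
            if c not in seen:
                seen.add(c)
                clusters.append(c)
        assigned = set().union(*clusters) if clusters else set()
        for node in nodes:  # stragglers become singletons
            if node not in assigned:
                clusters.append(frozenset([node]))
        return sorted(clusters, key=lambda c: (-len(c), tuple(sorted(map(str, c)))))

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def mcl_cluster(
    snapshot: Snapshot, params: MCLParams | None = None
) -> list[frozenset[str]]:
    """Run MCL on one snapshot; every node lands in >= 1 cluster.
    An empty snapshot yields an empty list."""
    params = params or MCLParams()
    mcl = MarkovClustering(**params.__dict__)
    return list(mcl.fit(snapshot).clusters_)


def filter_redundant(
    predicted: PredictedComplexSet, similarity_threshold: float
) -> PredictedComplexSet:
    """Size-ordered redundancy filter.

    Complexes are processed in descending size order (ties broken by the
    lexicographic order of sorted member lists).  Each retained complex
    discards every later — hence smaller-or-equal — complex whose
    overlapping score with it reaches the threshold.  The largest complex
    is never discarded and filtering is idempotent.
    """
    if not 0.0 < similarity_threshold <= 1.0:
        raise ValueError("similarity_threshold must be in (0, 1]")
    ordered = sorted(
        predicted.catalog.complexes,
        key=lambda lc: (-len(lc[1]), tuple(sorted(lc[1]))),
    )
    kept: list[tuple[str, frozenset[str]]] = []
    for label, members in ordered:
        if any(
            overlap_score(members, km) >= similarity_threshold
            for _, km in kept
        ):
            continue
        kept.append((label, members))
    return PredictedComplexSet(
        ComplexCatalog(kept),
        {label: predicted.provenance.get(label, frozenset())
         for label, _ in kept},
    )


def mine_temporal_complexes(
    net: TemporalNetwork,
    algorithm: ClustererFn | MarkovClustering | None = None,
    similarity_threshold: float = 1.0,
) -> PredictedComplexSet:
    """Cluster every snapshot, merge the per-snapshot groups, wipe out
    single-protein clusters, and apply the redundancy filter.

    Provenance records, per retained member set, every snapshot that
    produced that identical set.
    """
    if algorithm is None:
        algorithm = MarkovClustering()
    if isinstance(algorithm, MarkovClustering):
        base = algorithm

        def clusterer(snap: Snapshot) -> Iterable[frozenset[str]]:
            return MarkovClustering(**base.get_params()).fit(snap).clusters_
    else:
        clusterer = algorithm

    merged: dict[frozenset[str], set[int]] = {}
    for snap in net:
        for cluster in clusterer(snap):
            cluster = frozenset(cluster)
            if len(cluster) < 2:
                continue
            merged.setdefault(cluster, set()).add(snap.timepoint)

    ordered = sorted(merged, key=lambda c: (-len(c), tuple(sorted(c))))
    width = max(4, len(str(len(ordered))))
    labelled = [(f"P{i:0{width}d}", members)
                for i, members in enumerate(ordered, start=1)]
    predicted = PredictedComplexSet(
        ComplexCatalog(labelled),
        {label: frozenset(merged[members]) for label, members in labelled},
    )
    return filter_redundant(predicted, similarity_threshold)


class TemporalComplexMiner:
    """Estimator facade over :func:`mine_temporal_complexes`.

    ``fit`` stores the mined complexes as ``predicted_`` (a
    :class:`PredictedComplexSet`); ``fit_predict`` returns the member sets.
    """

    def __init__(
        self,
        similarity_threshold: float = 1.0,
        inflation: float = 2.0,
        self_loop_weight: float = 1.0,
        prune_threshold: float = 1e-5,
        max_iterations: int = 100,
        convergence_tol: float = 1e-6,
    ) -> None:
        self.similarity_threshold = similarity_threshold
        self.inflation = inflation
        self.self_loop_weight = self_loop_weight
        self.prune_threshold = prune_threshold
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "similarity_threshold": self.similarity_threshold,
            "inflation": self.inflation,
            "self_loop_weight": self.self_loop_weight,
            "prune_threshold": self.prune_threshold,
            "max_iterations": self.max_iterations,
            "convergence_tol": self.convergence_tol,
        }

    def set_params(self, **params) -> "TemporalComplexMiner":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, net: TemporalNetwork, y=None) -> "TemporalComplexMiner":
        mcl_kwargs = {k: v for k, v in self.get_params().items()
                      if k != "similarity_threshold"}
        self.predicted_ = mine_temporal_complexes(
            net,
            MarkovClustering(**mcl_kwargs),
            self.similarity_threshold,
        )
        return self

    def fit_predict(self, net: TemporalNetwork, y=None) -> list[frozenset[str]]:
        return self.fit(net).predicted_.catalog.member_sets()
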