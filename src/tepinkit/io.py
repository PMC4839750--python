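"""Readers and writers for the four tabular input formats plus pipeline
artifacts.

All dialects are UTF-8, whitespace- or tab-separated, with ``#`` comment
lines.  ID matching is exact, case-sensitive string equality after
whitespace trimming; mapping probes to protein IDs is the caller's job.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationMap,
    ComplexCatalog,
    ExpressionMatrix,
    Snapshot,
    StaticPIN,
    TemporalNetwork,
    canonical_edge,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input line, reported with file and line number."""


def _data_lines(path: str | os.PathLike[str]):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_ppi(path: str | os.PathLike[str]) -> StaticPIN:
    """Read a two-column edge list into a StaticPIN.

    Self-interactions and repeated (unordered-duplicate) pairs are dropped
    and counted; proteins appearing only in self-loops are not added.
    """
    edges: set[tuple[str, str]] = set()
    n_self = n_dup = 0
    seen_any = False
    for lineno, line in _data_lines(path):
        seen_any = True
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 fields")
        u, v = fields[0], fields[1]
        if u == v:
            n_self += 1
            continue
        e = canonical_edge(u, v)
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
    if not seen_any:
        raise ParseError(f"{path}: empty PPI file")
    if n_self or n_dup:
        logger.info(
            "read_ppi(%s): dropped %d self-interactions and %d duplicate pairs",
            path, n_self, n_dup,
        )
    proteins = frozenset(p for e in edges for p in e)
    return StaticPIN(proteins, frozenset(edges))


def write_ppi(pin: StaticPIN, path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(pin.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression(path: str | os.PathLike[str]) -> ExpressionMatrix:
    """Read a TSV expression matrix: header of time-point labels, then one
    row per gene.  Duplicate gene IDs (multiple probes) are collapsed to
    their per-time-point arithmetic mean with a logged warning."""
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if header is None:
            header = [f.strip() for f in fields]
            continue
        gene = fields[0].strip()
        values = fields[1:]
        if len(values) != len(header) - 1 and len(values) != len(header):
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(values)} values, "
                f"expected {len(header) - 1})"
            )
        if len(values) == len(header):  # header without a leading ID column
            header = ["gene"] + header
        parsed: list[float] = []
        for col, cell in enumerate(values, start=2):
            try:
                parsed.append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell in column {col}: {cell!r}"
                ) from exc
        genes.append(gene)
        rows.append(parsed)
    if header is None or not genes:
        raise ParseError(f"{path}: empty expression file")
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=genes,
                      columns=header[1:])
    if df.index.has_duplicates:
        n_dup = len(df) - df.index.nunique()
        logger.warning(
            "read_expression(%s): %d duplicate gene IDs collapsed to per-"
            "time-point means", path, n_dup,
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(str(c) for c in expr.data.columns) + "\n")
        for gene, row in zip(expr.genes, expr.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_complexes(path: str | os.PathLike[str]) -> ComplexCatalog:
    """Read one complex per line: label then member IDs.

    Duplicate members within a line are collapsed; single-protein complexes
    are excluded with a logged count."""
    complexes: list[tuple[str, frozenset[str]]] = []
    n_singleton = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            if len(fields) == 1:
                n_singleton += 1  # label with no members, or bare singleton
            continue
        label, members = fields[0], frozenset(fields[1:])
        if len(members) < 2:
            n_singleton += 1
            continue
        complexes.append((label, members))
    if n_singleton:
        logger.info(
            "read_complexes(%s): dropped %d single-protein complexes",
            path, n_singleton,
        )
    return ComplexCatalog(complexes)


def write_complexes(catalog: ComplexCatalog, path: str | os.PathLike[str]) -> None:
    """One complex per line: label then sorted member IDs."""
    with open(path, "w", encoding="utf-8") as fh:
        for label, members in catalog:
            fh.write(label + "\t" + "\t".join(sorted(members)) + "\n")


def read_annotation(
    path: str | os.PathLike[str], genome_size: int | None = None
) -> AnnotationMap:
    """Read a term -> member-IDs TSV.  If ``genome_size`` is not given it
    defaults to the size of the annotated universe."""
    terms: dict[str, frozenset[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: term with no members")
        terms[fields[0]] = frozenset(fields[1:])
    universe = set().union(*terms.values()) if terms else set()
    return AnnotationMap(terms, genome_size or len(universe))


def write_annotation(ann: AnnotationMap, path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# genome_size={ann.genome_size}\n")
        for term in sorted(ann.terms):
            fh.write(term + "\t" + "\t".join(sorted(ann.terms[term])) + "\n")


def write_tepin(net: TemporalNetwork, out_dir: str | os.PathLike[str]) -> None:
    """Serialize a temporal network: one edge-list file per time point plus
    a manifest TSV.  Isolated nodes are listed so the node policy survives
    the round trip; weighted edges carry a third column."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.tsv", "w", encoding="utf-8") as mf:
        mf.write("timepoint\tfile\tnodes\tedges\n")
        for snap in net:
            name = f"snapshot_{snap.timepoint:02d}.tsv"
            mf.write(f"{snap.timepoint}\t{name}\t{snap.n_nodes}\t{snap.n_edges}\n")
            weights = snap.weights
            with open(out / name, "w", encoding="utf-8") as fh:
                for node in sorted(n for n in snap.graph.nodes
                                   if snap.graph.degree(n) == 0):
                    fh.write(f"{node}\n")
                for e in sorted(snap.edges):
                    if e in weights:
                        fh.write(f"{e[0]}\t{e[1]}\t{weights[e]:.6g}\n")
                    else:
                        fh.write(f"{e[0]}\t{e[1]}\n")


def read_tepin(in_dir: str | os.PathLike[str]) -> TemporalNetwork:
    import networkx as nx

    manifest = pd.read_csv(Path(in_dir) / "manifest.tsv", sep="\t")
    snapshots = []
    for _, rec in manifest.sort_values("timepoint").iterrows():
        g = nx.Graph()
        for _, line in _data_lines(Path(in_dir) / rec["file"]):
            fields = line.split()
            if len(fields) == 1:
                g.add_node(fields[0])
            elif len(fields) == 2:
                g.add_edge(fields[0], fields[1])
            else:
                g.add_edge(fields[0], fields[1], weight=float(fields[2]))
        snapshots.append(Snapshot(int(rec["timepoint"]), g))
    return TemporalNetwork(snapshots)
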