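# tepinkit

Temporal protein complexes from time-evolving protein interaction networks.

Static protein–protein interaction (PPI) maps record *that* two proteins can
interact, not *when*. Complexes assemble and disassemble over the cell's
metabolic and division cycles, so clustering a static network mixes
machinery that never coexists. `tepinkit` integrates a static PPI network
with a gene-expression time course to build a **time-evolving protein
interaction network** — one snapshot subgraph per time point, induced on the
proteins active there — weights each snapshot's edges with complex-derived
affinity plus co-expression, mines temporal complexes with Markov
clustering, and evaluates predictions against a known-complex catalog.

It is aimed at computational biologists studying dynamic interactome
organisation who have (a) an undirected PPI edge list, (b) an expression
matrix over ordered time points, and (c) optionally a complex catalog and a
functional annotation map.

## The model

**Activity (deviation degree).** For gene *i* with expression *exp_it* over
*n* time points, let *u_i* be the arithmetic mean and *σ_i* the sample
standard deviation (denominator *n* − 1). Gene *i* is active at time *t* iff

    exp_it > u_i + σ_i

Each gene's own profile sets its threshold, so constitutively low- or
high-expressed genes are neither filtered out wholesale nor declared
always-active; a constant profile is never active.

**Temporal network.** Snapshot *t* is the subgraph of the static PIN induced
on the proteins active at *t*. Active proteins whose partners are all
inactive remain as isolated nodes (clustering ignores them).

**Edge weights.** For a known complex *k* with *N_k* members and *R_k*
induced static-PIN interactions among them, every induced interaction gets
connected coefficient *CC_k* = *N_k*/*R_k*; an edge's connected affinity
coefficient is CAC_ij = Σ_k CC_k over the complexes containing the edge.
With PCC_ij the Pearson correlation of the two full expression profiles,
the edge weight is

    W_ij = CAC_ij + PCC_ij

and edges with W ≤ 0 are eliminated as likely false positives.

**Mining.** Markov clustering (expansion/inflation of the column-stochastic
flow matrix) runs on every snapshot; the per-snapshot results are merged,
single-protein clusters wiped out, and a size-descending redundancy filter
drops any complex whose overlapping score with a larger retained one
reaches the similarity threshold (1.0 by default).

**Evaluation.** Predicted complex *pc* matches known *kc* iff
OS(pc, kc) = |pc ∩ kc|² / (|pc|·|kc|) ≥ 0.2. With TP matched predictions,
FP unmatched ones and FN = #known − MKC unmatched known complexes:
Sn = TP/(TP+FN), Sp = TP/(TP+FP), F = 2·Sn·Sp/(Sn+Sp). Function enrichment
uses the exact hypergeometric tail p-value with significance cutoff 0.01.

## Worked example

```python
from tepinkit import (SynthConfig, generate, active_sets, build_tepin,
                      weight_network, mine_temporal_complexes, evaluate,
                      network_properties)

data = generate(SynthConfig(n_proteins=120, n_complexes=8, seed=42))
print("PIN:", data.pin.n_proteins, "proteins,", data.pin.n_edges, "edges")
schedule = active_sets(data.expression)
net = build_tepin(data.pin, schedule)
print(network_properties(net).tail(1).to_string(index=False))
weighted, elim = weight_network(net, data.pin, data.expression, data.known)
print(f"mean elimination ratio: {elim.mean():.3f}")
predicted = mine_temporal_complexes(weighted)
print("predicted complexes:", len(predicted))
report = evaluate(predicted.catalog, data.known)
print(f"Sn={report.Sn:.3f} Sp={report.Sp:.3f} F={report.F:.3f} "
      f"perfect={report.match.perfect}/{report.match.n_known}")
```

prints

```
PIN: 101 proteins, 231 edges
timepoint  nodes     edges  density
  average  15.25 23.805556 0.124502
mean elimination ratio: 0.012
predicted complexes: 12
Sn=1.000 Sp=0.917 F=0.957 perfect=8/8
```

The generator plants 8 complexes, each co-activated in a contiguous window
of the 36-point time course. Snapshots average ~15 proteins (only the
currently active slice of the 101-protein network) and are an order of
magnitude denser than the static PIN. Weighting removes ~1% of snapshot
edges as anti-correlated or unsupported; the mined catalog recovers all 8
planted complexes exactly (8 perfect matches), with one near-duplicate
prediction costing some specificity.

The same chain is available from the shell:

```sh
tepinkit synth --seed 42 --n-proteins 120 --n-complexes 8 --out fx/
tepinkit run --pin fx/pin.tsv --expr fx/expression.tsv \
             --complexes fx/known_complexes.tsv --out out/
```

Stage summaries land in `out/summary.jsonl`; the `activity`, `build`,
`weight`, `mine`, `evaluate` and `enrich` subcommands expose the individual
stages. Estimator classes (`DeviationDegreeDetector`, `MarkovClustering`,
`ConnectedAffinityWeighter`, `TemporalComplexMiner`) follow the
scikit-learn `fit`/`transform`/`get_params` protocol for composition.

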