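# Methods

## Model and assumptions

The package treats protein activity as a per-gene excursion problem on an
expression time course. The working assumptions are:

* **Just-in-time assembly.** Complex subunits are jointly present around
  the time the complex functions, so a protein's interactions are
  meaningful only at the time points where the protein is active.
* **Deviation-degree activity.** Gene *i* is active at time *t* iff
  *exp_it* > *u_i* + *σ_i*, with *u_i* the arithmetic mean and *σ_i* the
  sample standard deviation (*n* − 1 denominator) of its own profile. The
  inequality is strict: "above the threshold" excludes equality, so a
  zero-variance profile is active nowhere. Because mean and SD transform
  consistently under positive affine maps, the active set is invariant
  under rescaling/shifting a profile — the rule responds to profile shape,
  not expression level.
* **Snapshots are induced subgraphs.** Snapshot *t* keeps exactly the
  active proteins and the static-PIN edges among them. Isolated active
  proteins are kept as nodes (the construction reserves proteins first,
  then their interactions); they are counted in node statistics but cannot
  join a multi-protein cluster, and any singleton cluster they produce is
  wiped out downstream.
* **Edge quality is heterogeneous.** W = CAC + PCC combines catalog
  support with co-expression; an edge with non-positive weight (strictly,
  W ≤ 0) is eliminated as a likely false positive.

## Conventions with alternatives, and why these were chosen

* **R_k = induced static-PIN edges.** Complex catalogs list members, not
  interactions, so the number of interactions "within" complex *k* is read
  as the static-PIN edges induced on its member set. A complex inducing no
  edge has an undefined CC and contributes nothing (logged) rather than
  erroring. N_k is the full member count, even when members are absent
  from the PIN, because it is defined as the complex's protein count.
* **One PCC per edge**, computed on the full *n*-point profiles rather
  than per-snapshot windows: windowed correlations on 3–8 points would be
  extremely noisy, and a single coefficient matches the weighting model.
  If either endpoint lacks expression data the PCC term is 0 (absence of
  evidence), and a zero-variance profile likewise contributes 0 (the
  correlation is 0/0 there).
* **FN = #known − MKC.** "Known complexes matching none of the
  predictions" pairs each known complex with at most one FN count, and a
  predicted complex matching several known complexes counts once in TP.
  These conventions are the only ones that reproduce the published
  Sn/Sp/F triples from the corresponding printed counts (e.g. TP = 1599,
  #PC = 2906, MKC = 647 of 1063 gives Sn = 0.794, Sp = 0.550, F = 0.650),
  which the acceptance suite checks.
* **Redundancy filter uses OS with ≥.** The overlapping score is the only
  similarity the evaluation defines, and a strict `>` at the conventional
  threshold 1.0 would discard nothing (OS ≤ 1); `≥` makes exact duplicates
  collapse. Ties in the size ordering are broken by the lexicographic
  order of sorted member lists for determinism.
* **Average network density** is the arithmetic mean of per-snapshot
  densities, not the density of mean counts — mean counts of ~447 nodes /
  839 edges would give ≈ 0.0084 while the per-snapshot mean is ≈ 0.0088;
  only the latter convention is self-consistent with the reference
  statistics the tests encode.

## Markov clustering

Parameters (defaults are the community-standard ones; nothing in the
mining procedure prescribes others): inflation 2.0 (dimensionless;
granularity — higher splits finer), self-loop weight 1.0 (stabilises flow
and guarantees aperiodicity), prune threshold 1e-5 (entries below it are
zeroed after inflation, except each column's maximum, so columns are never
emptied), max 100 iterations, convergence when the max entry change drops
below 1e-6. Clusters are read off attractor rows (diagonal mass > 1e-6);
overlapping attractor supports yield overlapping clusters, and any node
left unassigned numerically becomes a singleton so every node is covered.
Flow cannot cross disconnected components, so MCL never merges them. With
fixed node ordering (nodes are sorted) the result is deterministic.

Degenerate inputs: an empty snapshot returns no clusters; negative edge
weights are rejected (the weighting stage guarantees positivity upstream).

## Hypergeometric enrichment

p = P(X ≥ k) for X hypergeometric(N, F, C) is evaluated as the direct sum
of the upper tail in log-space (`gammaln` + `logsumexp`): complexes are
small, so exactness is cheap, and log-space keeps 1e-40-scale p-values
accurate where the naive 1 − Σ form would round to 0 or go negative. The
genome size N defaults to the annotation map's declared universe and is
overridable. No multiple-testing correction is applied; p ≥ 0.01 is
reported as not significant. Complexes without any annotated member get
p = 1 and an `annotated = False` flag.

## Synthetic data: what it emulates and what it does not

`SynthConfig` defaults encode the strong-signal study conditions used for
the recovery experiment: 300 proteins, 20 planted complexes of 4–10
members, 36 time points (three 12-point cycles' worth of samples),
intra-complex edge probability 0.9, background edge probability 0.01,
2% spurious-edge injection and 5% edge dropout, expression baseline 5 with
activation amplitude 5 and Gaussian noise SD 1 (amplitude = 5× noise), and
contiguous activation windows of 3–8 time points — the range in which the
bulk of proteins' active-point counts fall in real time-course data.

The generator emulates: planted modular structure, co-expression confined
to activation windows, catalog-supported edges, and PIN false
positives/negatives. It does **not** emulate scale-free degree
distributions, overlapping complex membership, periodic (multi-cycle)
re-activation, probe-level measurement artifacts, or correlated noise.
Passing recovery tests therefore show the pipeline recovers rectangular
co-activation modules under Gaussian noise — a necessary sanity check, not
evidence about any particular real interactome.

With Gaussian noise, strict containment of each gene's active set in its
planted window is a statistical tendency, not a theorem: at the default
5× signal about 3% of active points stray outside windows (noise tails
exceed the per-gene threshold), while at 10× signal no strays were
observed across 30 seeds. The property tests assert exact containment in
the 10× regime and >90% bulk containment at the default.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery experiment at
300 proteins / 20 complexes / 36 time points over 20 seeds (~10 s total on
one core) — large enough that the weighted-temporal versus static contrast
is stable (weighted F ≈ 0.91 vs static ≈ 0.48 on these conditions), small
enough to iterate quickly. All randomness flows through a single seeded
NumPy generator per call; pipeline reruns with the same config are
byte-identical up to output paths.

## Known limitations

* Exact, case-sensitive ID matching: probe-to-protein mapping is the
  caller's responsibility (duplicate expression rows are collapsed to
  their mean, with a warning).
* All-pairs matching in evaluation is O(#predicted × #known) — fine for
  catalog scales (thousands), not for millions.
* The MCL implementation targets snapshot scales (10²–10⁴ nodes); it is
  sparse but single-threaded.
* External complex-detection algorithms are supported only through the
  pluggable clusterer callable; none are bundled.
* The three-sigma activity rule from prior dynamic-network work is not
  implemented (its exact formulas are not restated in the sources this
  package follows); the detector interface accepts any user-supplied rule
  in its place.
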