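"""Seeded generator of PIN / expression / complex-catalog triples with
planted temporal structure.

The generator emulates the study design the pipeline targets: a yeast-like
static interactome with dense planted complexes plus background noise
edges, a metabolic-cycle-like expression time course in which each
complex's members are jointly up-regulated inside a contiguous activation
window, a known-complex catalog equal to (or a corruption of) the planted
truth, and a one-term-per-complex annotation map.  Everything derives from
one seeded NumPy generator, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    AnnotationMap,
    ComplexCatalog,
    EvaluationReport,
    ExpressionMatrix,
    Snapshot,
    StaticPIN,
    TemporalNetwork,
    canonical_edge,
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults are the strong-signal regime: activation amplitude five times
    the noise SD, near-clique complexes (p_in = 0.9) on a sparse background
    (p_out = 0.01), contiguous activation windows of 3-8 of 36 time points.
    """

    n_proteins: int = 300
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (4, 10)
    n_timepoints: int = 36
    p_in: float = 0.9
    p_out: float = 0.01
    fp_rate: float = 0.02
    fn_rate: float = 0.05
    baseline: float = 5.0
    amplitude: float = 5.0
    noise_sd: float = 1.0
    window_length_range: tuple[int, int] = (3, 8)
    catalog_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "fp_rate", "fn_rate", "catalog_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("complex sizes must be >= 2 and lo <= hi")
        wlo, whi = self.window_length_range
        if not 1 <= wlo <= whi <= self.n_timepoints:
            raise ValueError("window lengths must fit within the time course")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 time points")


@dataclass
class SyntheticDataset:
    pin: StaticPIN
    expression: ExpressionMatrix
    known: ComplexCatalog
    truth: ComplexCatalog
    annotation: AnnotationMap
    windows: dict[str, tuple[int, int]] = field(default_factory=dict)


def generate(config: SynthConfig) -> SyntheticDataset:
    """Draw one dataset from the configured conditions.

    Complex member sets are disjoint; the PIN takes intra-complex edges
    with probability p_in and background edges with p_out, then injects
    false positives (fp_rate x current edges added at random) and false
    negatives (each edge independently deleted with fn_rate).  Member genes
    get ``baseline + amplitude`` inside their complex's window and
    ``baseline`` outside, plus Gaussian noise, so deviation-degree activity
    and pairwise co-expression are both concentrated inside the window.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    if sizes.sum() > config.n_proteins:
        raise ValueError(
            f"complexes need {int(sizes.sum())} proteins but only "
            f"{config.n_proteins} available"
        )
    width = len(str(config.n_proteins))
    proteins = [f"Y{i:0{width}d}" for i in range(config.n_proteins)]
    order = rng.permutation(config.n_proteins)

    members_of: list[frozenset[str]] = []
    cursor = 0
    for size in sizes:
        members_of.append(
            frozenset(proteins[j] for j in order[cursor:cursor + size])
        )
        cursor += int(size)

    complex_pairs: set[tuple[str, str]] = set()
    edges: set[tuple[str, str]] = set()
    for members in members_of:
        for u, v in itertools.combinations(sorted(members), 2):
            e = canonical_edge(u, v)
            complex_pairs.add(e)
            if rng.random() < config.p_in:
                edges.add(e)
    for u, v in itertools.combinations(proteins, 2):
        e = canonical_edge(u, v)
        if e in complex_pairs:
            continue
        if rng.random() < config.p_out:
            edges.add(e)

    # false positives: spurious edges added at fp_rate x current edge count
    n_fp = int(round(config.fp_rate * len(edges)))
    absent = sorted(set(
        e for e in (
            canonical_edge(proteins[i], proteins[j])
            for i, j in zip(
                rng.integers(0, config.n_proteins, size=4 * n_fp + 8),
                rng.integers(0, config.n_proteins, size=4 * n_fp + 8),
            )
            if i != j
        )
        if e not in edges
    ))
    for e in absent[:n_fp]:
        edges.add(e)
    # false negatives: each true edge independently dropped
    if config.fn_rate > 0:
        edges = {e for e in sorted(edges) if rng.random() >= config.fn_rate}

    pin = StaticPIN.from_edges(edges)

    windows: dict[str, tuple[int, int]] = {}
    labels = [f"C{k + 1:03d}" for k in range(config.n_complexes)]
    wlo, whi = config.window_length_range
    values = np.full(
        (config.n_proteins, config.n_timepoints), config.baseline, dtype=float
    )
    index = {p: i for i, p in enumerate(proteins)}
    for label, members in zip(labels, members_of):
        length = int(rng.integers(wlo, whi + 1))
        start = int(rng.integers(1, config.n_timepoints - length + 2))
        windows[label] = (start, start + length - 1)
        for p in sorted(members):
            values[index[p], start - 1:start + length - 1] += config.amplitude
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    expression = ExpressionMatrix.from_array(proteins, values)
    truth = ComplexCatalog(list(zip(labels, members_of)))
    if config.catalog_dropout > 0:
        keep = [lc for lc in truth.complexes
                if rng.random() >= config.catalog_dropout]
        known = ComplexCatalog(keep)
    else:
        known = ComplexCatalog(list(truth.complexes))
    annotation = AnnotationMap(
        {f"T:{label}": members for label, members in truth.complexes},
        genome_size=config.n_proteins,
    )
    return SyntheticDataset(pin, expression, known, truth, annotation, windows)


def _static_as_temporal(pin: StaticPIN) -> TemporalNetwork:
    return TemporalNetwork([Snapshot(1, pin.to_networkx())])


def recovery_experiment(config: SynthConfig) -> dict:
    """Run the full weighted-temporal pipeline and a static-PIN pipeline on
    one generated dataset, with identical clustering parameters, and report
    both accuracy summaries plus their F-measure difference."""
    from .activity import active_sets
    from .builder import build_tepin
    from .clustering import MarkovClustering, mine_temporal_complexes
    from .evaluation import evaluate
    from .weighting import weight_network

    data = generate(config)
    mcl = MarkovClustering()

    schedule = active_sets(data.expression)
    tepin = build_tepin(data.pin, schedule)
    weighted, elim = weight_network(
        tepin, data.pin, data.expression, data.known
    )
    predicted_w = mine_temporal_complexes(weighted, mcl, 1.0)
    report_w = evaluate(predicted_w.catalog, data.known)

    predicted_s = mine_temporal_complexes(_static_as_temporal(data.pin), mcl, 1.0)
    report_s = evaluate(predicted_s.catalog, data.known)

    return {
        "weighted_tepin": report_w,
        "static_pin": report_s,
        "f_difference": report_w.F - report_s.F,
        "elimination_ratios": elim,
        "dataset": data,
    }


def recovery_win_fraction(
    config: SynthConfig, n_seeds: int = 20, base_seed: int = 0
) -> dict:
    """Fraction of seeds where the weighted-temporal pipeline's F-measure
    is at least the static pipeline's, over ``n_seeds`` replicates."""
    wins = 0
    f_weighted: list[float] = []
    f_static: list[float] = []
    for s in range(n_seeds):
        out = recovery_experiment(replace(config, seed=base_seed + s))
        f_weighted.append(out["weighted_tepin"].F)
        f_static.append(out["static_pin"].F)
        if out["weighted_tepin"].F >= out["static_pin"].F:
            wins += 1
    return {
        "n_seeds": n_seeds,
        "wins": wins,
        "win_fraction": wins / n_seeds,
        "f_weighted": f_weighted,
        "f_static": f_static,
    }
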