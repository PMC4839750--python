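"""Evaluation of predicted complexes against a known catalog.

Matching uses the overlapping score OS(pc, kc) = |pc ∩ kc|² / (|pc| · |kc|);
a predicted/known pair is matched when OS reaches a threshold (0.2 by
convention in the complex-prediction literature; OS = 1 is a perfect
match).  From the match counts:

    Sn = TP / (TP + FN)        sensitivity — fraction of known complexes
                               recovered (FN = #known − MKC)
    Sp = TP / (TP + FP)        specificity — fraction of predictions that
                               match something known
    F  = 2·Sn·Sp / (Sn + Sp)   harmonic mean

Biological-significance testing is the one-sided hypergeometric tail: the
probability of drawing k or more annotated proteins when a complex of C
proteins is sampled from a genome of N proteins, F of which carry the term.
Computed exactly in log-space; no multiple-testing correction is applied
and p >= 0.01 is treated as not significant.
"""

from __future__ import annotations

import logging
from typing import AbstractSet

import numpy as np
from scipy.special import gammaln, logsumexp

from .datatypes import AnnotationMap, ComplexCatalog, EvaluationReport, MatchResult

logger = logging.getLogger(__name__)

PVALUE_BIN_EDGES = (1e-15, 1e-10, 1e-5, 0.01)
PVALUE_BIN_LABELS = ("<1e-15", "[1e-15,1e-10)", "[1e-10,1e-5)",
                     "[1e-5,0.01)", ">=0.01")


def overlap_score(pc: AbstractSet[str], kc: AbstractSet[str]) -> float:
    """|pc ∩ kc|² / (|pc| · |kc|): symmetric, in [0, 1], and 1 iff equal."""
    if not pc or not kc:
        raise ValueError("overlap score is undefined for empty complexes")
    inter = len(set(pc) & set(kc))
    return inter * inter / (len(pc) * len(kc))


def match_complexes(
    predicted: ComplexCatalog,
    known: ComplexCatalog,
    os_threshold: float = 0.2,
) -> MatchResult:
    """All-pairs overlap-score matching at the given threshold."""
    if not 0.0 < os_threshold <= 1.0:
        raise ValueError("os_threshold must be in (0, 1]")
    pred_sets = predicted.member_sets()
    known_sets = known.member_sets()
    matched_pred = np.zeros(len(pred_sets), dtype=bool)
    matched_known = np.zeros(len(known_sets), dtype=bool)
    perfect_known = np.zeros(len(known_sets), dtype=bool)
    for i, pc in enumerate(pred_sets):
        for j, kc in enumerate(known_sets):
            score = overlap_score(pc, kc)
            if score >= os_threshold:
                matched_pred[i] = True
                matched_known[j] = True
            if score == 1.0:
                perfect_known[j] = True
    tp = int(matched_pred.sum())
    mkc = int(matched_known.sum())
    return MatchResult(
        os_threshold=os_threshold,
        n_predicted=len(pred_sets),
        n_known=len(known_sets),
        TP=tp,
        FP=len(pred_sets) - tp,
        MKC=mkc,
        FN=len(known_sets) - mkc,
        perfect=int(perfect_known.sum()),
    )


def accuracy_metrics(
    match: MatchResult, average_predicted_size: float = float("nan")
) -> EvaluationReport:
    """Sn, Sp and F-measure from match counts; zero denominators yield 0."""
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s denominator is 0; reporting 0", name)
            return 0.0
        return num / den

    sn = ratio(match.TP, match.TP + match.FN, "Sn")
    sp = ratio(match.TP, match.TP + match.FP, "Sp")
    f = 2.0 * sn * sp / (sn + sp) if sn + sp > 0 else 0.0
    pct = (100.0 * match.MKC / match.n_known) if match.n_known else float("nan")
    return EvaluationReport(
        match=match, Sn=sn, Sp=sp, F=f,
        average_predicted_size=average_predicted_size,
        matched_known_percentage=pct,
    )


def matched_known_percentage(match: MatchResult, total_known: int | None = None) -> float:
    """100 · MKC / total_known."""
    total = match.n_known if total_known is None else total_known
    if total <= 0:
        raise ValueError("total_known must be positive")
    if total < match.MKC:
        raise ValueError("total_known smaller than MKC")
    return 100.0 * match.MKC / total


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def enrichment_pvalue(k: int, C: int, F: int, N: int) -> float:
    """Exact hypergeometric upper-tail probability of observing k or more
    term-annotated proteins in a complex of C proteins, when F of the N
    genome proteins carry the term.

    Evaluated as the direct sum of the upper tail in log-space (numerically
    stable for the tiny p-values complexes typically reach); k = 0 gives 1.
    """
    if not (0 <= k <= C <= N) or not (0 <= F <= N):
        raise ValueError("require 0 <= k <= C <= N and 0 <= F <= N")
    if k == 0:
        return 1.0
    i = np.arange(k, min(C, F) + 1, dtype=float)
    if len(i) == 0:
        return 0.0
    log_terms = (
        _log_binom(F, i) + _log_binom(N - F, C - i) - _log_binom(N, C)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def annotate_complexes(
    predicted: ComplexCatalog,
    ann: AnnotationMap,
    alpha: float = 0.01,
    genome_size: int | None = None,
) -> dict:
    """Best-term enrichment per predicted complex.

    For each complex, the minimum p-value over all annotation terms (with
    its term) is reported, together with a significance flag (p < alpha)
    and counts of complexes binned by p-value interval.  A complex none of
    whose members is annotated gets p = 1 and is flagged as unannotated.
    """
    N = genome_size if genome_size is not None else ann.genome_size
    results: dict[str, dict] = {}
    bin_counts = dict.fromkeys(PVALUE_BIN_LABELS, 0)
    for label, members in predicted:
        best_p, best_term = 1.0, None
        annotated = False
        for term, term_set in ann.terms.items():
            k = len(members & term_set)
            if k == 0:
                continue
            annotated = True
            p = enrichment_pvalue(k, len(members), len(term_set), N)
            if p < best_p or (p == best_p and best_term is None):
                best_p, best_term = p, term
        bin_label = PVALUE_BIN_LABELS[
            int(np.searchsorted(PVALUE_BIN_EDGES, best_p, side="right"))
        ]
        bin_counts[bin_label] += 1
        results[label] = {
            "p_value": best_p,
            "term": best_term,
            "significant": best_p < alpha,
            "annotated": annotated,
        }
    n_sig = sum(1 for r in results.values() if r["significant"])
    return {
        "per_complex": results,
        "bins": bin_counts,
        "n_significant": n_sig,
        "significant_percentage": (
            100.0 * n_sig / len(results) if results else float("nan")
        ),
        "alpha": alpha,
        "genome_size": N,
    }


def evaluate(
    predicted: ComplexCatalog,
    known: ComplexCatalog,
    os_threshold: float = 0.2,
) -> EvaluationReport:
    """Match + accuracy in one call."""
    sizes = [len(m) for m in predicted.member_sets()]
    return accuracy_metrics(
        match_complexes(predicted, known, os_threshold),
        average_predicted_size=float(np.mean(sizes)) if sizes else float("nan"),
    )
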