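"""Overlap-score matching, accuracy bookkeeping, and hypergeometric
enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from tepinkit import (
    AnnotationMap,
    ComplexCatalog,
    MatchResult,
    accuracy_metrics,
    annotate_complexes,
    enrichment_pvalue,
    evaluate,
    match_complexes,
    matched_known_percentage,
    overlap_score,
)


def catalog(*member_sets):
    return ComplexCatalog(
        [(f"c{i}", frozenset(m)) for i, m in enumerate(member_sets)]
    )


@pytest.mark.parametrize(
    "pc, kc, expected",
    [
        ({"a", "b", "c", "d", "e"}, {"a", "b", "c", "d", "e"}, 1.0),
        ({"a", "b"}, {"x", "y"}, 0.0),
        ({"a", "b", "c", "d"}, {"a", "b", "x", "y", "z"}, 4 / 20),
    ],
)
def test_overlap_score_examples(pc, kc, expected):
    assert overlap_score(pc, kc) == pytest.approx(expected, abs=1e-12)


def test_overlap_score_empty_rejected():
    with pytest.raises(ValueError):
        overlap_score(set(), {"a"})


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.frozensets(st.integers(0, 15), min_size=1, max_size=10),
    st.frozensets(st.integers(0, 15), min_size=1, max_size=10),
)
def test_overlap_score_symmetry_and_bounds(pc, kc):
    s = overlap_score(pc, kc)
    assert s == overlap_score(kc, pc)
    assert 0.0 <= s <= min(len(pc), len(kc)) / max(len(pc), len(kc))
    assert (s == 1.0) == (pc == kc)


def brute_force_match(predicted, known, thr):
    tp = sum(
        1 for pc in predicted.member_sets()
        if any(overlap_score(pc, kc) >= thr for kc in known.member_sets())
    )
    mkc = sum(
        1 for kc in known.member_sets()
        if any(overlap_score(pc, kc) >= thr for pc in predicted.member_sets())
    )
    perfect = sum(
        1 for kc in known.member_sets()
        if any(overlap_score(pc, kc) == 1.0 for pc in predicted.member_sets())
    )
    return tp, mkc, perfect


def test_match_identical_and_disjoint_catalogs():
    c = catalog({"a", "b"}, {"c", "d", "e"})
    m = match_complexes(c, c, 0.2)
    assert (m.TP, m.FP, m.FN, m.perfect) == (2, 0, 0, 2)

    other = catalog({"x", "y"}, {"z", "w"})
    m = match_complexes(c, other, 0.2)
    assert (m.TP, m.MKC) == (0, 0)


def test_match_against_brute_force_oracle(rng):
    for _ in range(10):
        pred = catalog(*[
            set(rng.choice(25, size=rng.integers(2, 7), replace=False).tolist())
            for _ in range(rng.integers(1, 30))
        ])
        known = catalog(*[
            set(rng.choice(25, size=rng.integers(2, 7), replace=False).tolist())
            for _ in range(rng.integers(1, 30))
        ])
        thr = float(rng.choice([0.2, 0.5, 1.0]))
        m = match_complexes(pred, known, thr)
        tp, mkc, perfect = brute_force_match(pred, known, thr)
        assert (m.TP, m.MKC, m.perfect) == (tp, mkc, perfect)
        # conservation identities
        assert m.TP + m.FP == len(pred)
        assert m.MKC + m.FN == len(known)


def test_raising_threshold_is_monotone(small_dataset):
    pred = ComplexCatalog(small_dataset.truth.complexes[:10])
    known = small_dataset.known
    prev_tp, prev_mkc = np.inf, np.inf
    for thr in (0.2, 0.4, 0.6, 0.8, 1.0):
        m = match_complexes(pred, known, thr)
        assert m.TP <= prev_tp and m.MKC <= prev_mkc
        prev_tp, prev_mkc = m.TP, m.MKC


def result(tp, fp, mkc, fn, n_known=None, perfect=0):
    return MatchResult(
        os_threshold=0.2, n_predicted=tp + fp,
        n_known=(mkc + fn) if n_known is None else n_known,
        TP=tp, FP=fp, MKC=mkc, FN=fn, perfect=perfect,
    )


def test_accuracy_bookkeeping_reproduces_published_identities():
    """FN = #known - MKC makes the printed Sn/Sp/F identities consistent:
    2906 predictions with 1599 matched and 647 of 1063 known recovered give
    Sn 0.794, Sp 0.550, F 0.650; 1630 predictions with 672 matched and 568
    recovered give Sn 0.576."""
    r = accuracy_metrics(result(1599, 2906 - 1599, 647, 1063 - 647))
    assert r.Sn == pytest.approx(0.794, abs=5e-4)
    assert r.Sp == pytest.approx(0.550, abs=5e-4)
    assert r.F == pytest.approx(0.650, abs=5e-4)

    r = accuracy_metrics(result(672, 1630 - 672, 568, 1063 - 568))
    assert r.Sn == pytest.approx(0.576, abs=5e-4)
    assert r.Sp == pytest.approx(0.412, abs=5e-4)
    assert r.F == pytest.approx(0.481, abs=5e-4)


def test_accuracy_zero_tp():
    r = accuracy_metrics(result(0, 5, 0, 3))
    assert (r.Sn, r.Sp, r.F) == (0.0, 0.0, 0.0)


def test_f_between_bounds(rng):
    for _ in range(50):
        tp = int(rng.integers(1, 50))
        fp = int(rng.integers(0, 50))
        fn = int(rng.integers(0, 50))
        r = accuracy_metrics(result(tp, fp, tp, fn, n_known=tp + fn))
        assert 0.0 <= r.F <= 1.0
        if r.Sn > 0 and r.Sp > 0:
            assert min(r.Sn, r.Sp) <= r.F <= 2 * min(r.Sn, r.Sp)


def test_matched_known_percentage():
    assert matched_known_percentage(
        result(600, 0, 505, 1063 - 505), 1063
    ) == pytest.approx(47.5, abs=0.05)
    assert matched_known_percentage(
        result(700, 0, 647, 1063 - 647), 1063
    ) == pytest.approx(60.9, abs=0.05)
    assert matched_known_percentage(result(0, 1, 0, 5), 5) == 0.0
    with pytest.raises(ValueError):
        matched_known_percentage(result(0, 1, 0, 0, n_known=0), 0)


def test_enrichment_pvalue_examples():
    assert enrichment_pvalue(0, 5, 3, 100) == 1.0
    # N=10, F=5, C=2, k=2: 1 - [C(5,0)C(5,2) + C(5,1)C(5,1)]/C(10,2) = 10/45
    assert enrichment_pvalue(2, 2, 5, 10) == pytest.approx(10 / 45, rel=1e-12)
    with pytest.raises(ValueError):
        enrichment_pvalue(3, 2, 5, 10)


def test_enrichment_matches_hypergeom_sf(rng):
    """Exact log-space tail equals the survival function of the
    hypergeometric distribution on 500 random parameter draws."""
    for _ in range(500):
        N = int(rng.integers(2, 5000))
        F = int(rng.integers(0, N + 1))
        C = int(rng.integers(1, min(N, 80) + 1))
        k = int(rng.integers(0, C + 1))
        p = enrichment_pvalue(k, C, F, N)
        expected = float(hypergeom.sf(k - 1, N, F, C))
        assert p == pytest.approx(expected, rel=1e-9, abs=1e-300)


def test_annotate_complexes_bins_and_flags():
    ann = AnnotationMap(
        {"t1": frozenset(f"p{i}" for i in range(10))}, genome_size=2000
    )
    predicted = catalog(
        {"p0", "p1", "p2", "p3", "p4", "p5"},   # fully inside t1: tiny p
        {"q1", "q2"},                            # unannotated: p = 1
    )
    out = annotate_complexes(predicted, ann, alpha=0.01)
    tiny = out["per_complex"]["c0"]
    assert tiny["significant"] and tiny["term"] == "t1"
    assert tiny["p_value"] < 1e-12
    unann = out["per_complex"]["c1"]
    assert unann["p_value"] == 1.0 and not unann["significant"]
    assert not unann["annotated"]
    assert sum(out["bins"].values()) == len(predicted)
    assert out["n_significant"] == 1
    assert out["significant_percentage"] == pytest.approx(50.0)


def test_evaluate_end_to_end():
    known = catalog({"a", "b", "c"}, {"d", "e"})
    pred = catalog({"a", "b", "c"}, {"x", "y"})
    report = evaluate(pred, known, 0.2)
    assert report.match.TP == 1 and report.match.FP == 1
    assert report.match.MKC == 1 and report.match.FN == 1
    assert report.Sn == pytest.approx(0.5)
    assert report.average_predicted_size == pytest.approx(2.5)
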