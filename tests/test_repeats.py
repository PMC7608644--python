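"""Tandem-repeat detection and MEI/VNTR/other classification."""

from __future__ import annotations

import numpy as np
import pytest

from svscape._kernels import wraparound_local
from svscape.config import PipelineConfig, TrfWeights
from svscape.core import SvClass, SvLocus, TandemRepeat
from svscape.repeats import (
    _codes,
    _phase_consensus,
    classify_all,
    classify_mei,
    classify_vntr,
    detect_tandem_repeat,
    variable_alleles,
)

CFG = PipelineConfig()
W = TrfWeights()


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _sv(alleles, chrom="chr1", start=0, end=0, spanned=None):
    return SvLocus(
        chrom=chrom,
        start=start,
        end=end or start + len(alleles[0]),
        alleles=list(alleles),
        spanned=spanned or (True,) * len(alleles),
        is_sv=True,
    )


def brute_wrap(seq: str, cons: str, match=2, mism=7, ind=7) -> float:
    """Plain-python local wraparound DP (independent of the kernel)."""
    n, p = len(seq), len(cons)
    H = [[0.0] * (p + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, p + 1):
            jm1 = j - 1 if j > 1 else p
            sub = match if seq[i - 1] == cons[j - 1] else -mism
            v = max(H[i - 1][jm1] + sub, H[i - 1][j] - ind)
            if j > 1:
                v = max(v, H[i][j - 1] - ind)
            H[i][j] = max(v, 0.0)
            best = max(best, H[i][j])
    return best


def test_wraparound_matches_plain_python_dp():
    rng = np.random.default_rng(7)
    for _ in range(40):
        seq = _rand(rng, int(rng.integers(4, 61)))
        for p in range(1, min(20, len(seq)) + 1):
            cons = _phase_consensus(seq, p)
            score, _, _ = wraparound_local(_codes(seq), _codes(cons), 2.0, 7.0, 7.0)
            assert score == brute_wrap(seq, cons)


def test_perfect_tetramer_analytics():
    rep = detect_tandem_repeat("ACGT" * 5, W)
    assert (rep.period, rep.copies, rep.score) == (4, 5.0, 40)
    assert rep.gc == 0.5 and rep.entropy == 2.0 and rep.span_fraction == 1.0


def test_short_homopolymer_below_min_score():
    assert detect_tandem_repeat("A" * 9, W) is None  # score 18 < 20
    assert detect_tandem_repeat("", W) is None
    rep = detect_tandem_repeat("A" * 10, W)
    assert rep is not None and rep.period == 1 and rep.score == 20


def test_consensus_collapses_to_primitive_period():
    rep = detect_tandem_repeat("ACGACG" * 8, W)
    assert rep.period == 3 and rep.consensus == "ACG"


def test_long_array_candidate_path():
    unit = "ACGGTTACAGGCATTACCGGTTAAGCAT"  # 28 bp, above exhaustive length
    rep = detect_tandem_repeat(unit * 40 + "TTGAC", W)
    assert rep.period == 28 and rep.span_fraction > 0.9
    # 5% point mutations must not break detection
    arr = list(unit * 40)
    rng = np.random.default_rng(1)
    for i in rng.choice(len(arr), size=len(arr) // 20, replace=False):
        arr[int(i)] = "T" if arr[int(i)] != "T" else "A"
    rep2 = detect_tandem_repeat("".join(arr), W)
    assert rep2 is not None and rep2.period == 28


def test_random_sequence_mostly_repeat_free():
    rng = np.random.default_rng(5)
    hits = sum(
        detect_tandem_repeat(_rand(rng, 60), W) is not None for _ in range(500)
    )
    assert hits / 500 <= 0.02


def test_variable_alleles_strip_common_flanks():
    diffs = variable_alleles(["ACCGT", "AC" + "G" * 50 + "CGT", "ACCGT"], (True,) * 3)
    assert diffs == ["G" * 50]
    assert variable_alleles(["AAA", "AAA"], (True, True)) == []


def test_mei_identity_truncated_and_nested():
    rng = np.random.default_rng(3)
    element = _rand(rng, 300)
    lib = [("Alu-like", element)]
    flank = "ACCGT"
    carrier = flank[:2] + element + flank[2:]
    sv = _sv([flank, carrier, flank, flank, flank], start=100, end=105)
    assert classify_mei(sv, lib, CFG) == "Alu-like"
    # 240 bp truncation plus 10 bp of extra sequence still passes 80/80
    trunc = element[60:] + "ACGTAGGCTA"
    assert classify_mei(_sv(["", trunc]), lib, CFG) == "Alu-like"
    # the same element nested in a 1200 bp compound allele fails coverage
    comp = _rand(rng, 450) + element + _rand(rng, 450)
    assert classify_mei(_sv(["", comp]), lib, CFG) is None
    assert classify_mei(sv, [], CFG) is None


def test_mei_precedence_over_vntr():
    # an element that is itself tandem-structured: MEI wins over VNTR
    unit = "ACGGTTACAGGCATTACCGG"
    element = unit * 15
    sv = _sv(["", element])
    fractions = classify_all([sv], [("SVA-like", element)], None, CFG)
    assert sv.svclass is SvClass.MEI and sv.mei_family == "SVA-like"
    assert fractions == {"MEI": 1.0}


def test_vntr_span_and_track_rules():
    unit = "ACGGTTACAGGCATTACCGGTTAAGCAT"
    is_vntr, rep = classify_vntr(_sv([unit * 10, unit * 14]), None, CFG)
    assert is_vntr and rep.period == 28
    # non-repetitive indel allele: VNTR only via the reference track
    rng = np.random.default_rng(11)
    sv = _sv([_rand(rng, 60), ""], start=1000, end=1060)
    assert classify_vntr(sv, [("chr1", 950, 1100)], CFG)[0]
    assert not classify_vntr(sv, [("chr1", 0, 100)], CFG)[0]
    assert not classify_vntr(sv, [("chr2", 950, 1100)], CFG)[0]


def test_vntr_span_fraction_strictly_greater(monkeypatch):
    import svscape.repeats as repeats

    def fake(allele, weights=None, _frac=[0.5]):
        return TandemRepeat(
            period=4, consensus="ACGT", copies=10.0, score=80,
            gc=0.5, entropy=2.0, span_fraction=_frac[0],
        )

    monkeypatch.setattr(repeats, "detect_tandem_repeat", fake)
    sv = _sv(["A" * 80, "A" * 200])
    assert not classify_vntr(sv, None, CFG)[0]  # exactly half: not a VNTR

    def fake_above(allele, weights=None):
        return TandemRepeat(
            period=4, consensus="ACGT", copies=10.0, score=80,
            gc=0.5, entropy=2.0, span_fraction=0.5 + 1e-9,
        )

    monkeypatch.setattr(repeats, "detect_tandem_repeat", fake_above)
    assert classify_vntr(sv, None, CFG)[0]


def test_classify_all_fractions_and_empty():
    assert classify_all([], [], None, CFG) == {}
    rng = np.random.default_rng(13)
    unit = "ACGGTTACAGGCATT"
    svs = [
        _sv(["", unit * 20]),
        _sv(["", _rand(rng, 400)]),
        _sv([_rand(rng, 200), ""], start=500, end=700),
    ]
    skipped = _sv(["A", "A"])
    skipped.is_sv = False
    fractions = classify_all(svs + [skipped], [], None, CFG)
    assert fractions == {"OTHER": 2 / 3, "VNTR": 1 / 3}
    assert skipped.svclass is SvClass.UNCLASSIFIED
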