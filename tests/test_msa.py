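"""Pair-HMM posteriors, consistency transform, progressive MSA, segmentation."""

from __future__ import annotations

import numpy as np
import pytest

from svscape.config import PairHmmParams, PipelineConfig
from svscape.msa import (
    MsaWithConfidence,
    _padded_emissions,
    align_bubble,
    compute_posteriors,
    consistency_transform,
    pair_posteriors,
    progressive_align,
    segment_variants,
)

PARAMS = PairHmmParams()
CFG = PipelineConfig()


def brute_posterior(x: str, y: str, params: PairHmmParams = PARAMS):
    """Posterior match probabilities by explicit enumeration of every pair-HMM
    path (independent of the forward-backward kernel)."""
    code = {b: i for i, b in enumerate("ACGTN")}
    trans, init = params.transitions, params.initial
    em_m, em_i = _padded_emissions(params)
    xc = [code[b] for b in x]
    yc = [code[b] for b in y]
    n, m = len(x), len(y)
    total = 0.0
    post = np.zeros((n, m))

    def rec(i, j, prev, w, matches):
        nonlocal total
        if i == n and j == m:
            total += w
            for a, b in matches:
                post[a, b] += w
            return
        if i < n and j < m:
            p = (init[0] if prev is None else trans[prev, 0]) * em_m[xc[i], yc[j]]
            rec(i + 1, j + 1, 0, w * p, matches + [(i, j)])
        if i < n and prev != 2:
            p = (init[1] if prev is None else trans[prev, 1]) * em_i[xc[i]]
            rec(i + 1, j, 1, w * p, matches)
        if j < m and prev != 1:
            p = (init[2] if prev is None else trans[prev, 2]) * em_i[yc[j]]
            rec(i, j + 1, 2, w * p, matches)

    rec(0, 0, None, 1.0, [])
    return post / total


def test_pair_posteriors_match_enumeration():
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(25):
        n, m = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        x = "".join(rng.choice(list("ACGTN"), n))
        y = "".join(rng.choice(list("ACGT"), m))
        err = float(np.abs(brute_posterior(x, y) - pair_posteriors(x, y, PARAMS)).max())
        worst = max(worst, err)
    assert worst < 1e-9


def test_identity_posterior_diagonal():
    p = pair_posteriors("ACGTACGT", "ACGTACGT", PARAMS)
    assert np.all(np.diag(p) > 0.99)


def test_empty_sequence_fully_unaligned():
    pset = compute_posteriors(["ACGT", ""], PARAMS)
    assert np.allclose(pset.gap_posterior(0, 1), 1.0)


def test_invalid_alphabet_names_position():
    with pytest.raises(ValueError, match="position 2"):
        pair_posteriors("ACXT", "ACGT", PARAMS)


def test_row_sums_after_consistency_transform():
    rng = np.random.default_rng(1)
    alleles = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(3)]
    pset = consistency_transform(compute_posteriors(alleles, PARAMS), n_rounds=2)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            sums = pset.row_sums(i, j)
            assert np.all(sums <= 1.0 + 1e-6)
            assert np.all(pset.gap_posterior(i, j) >= -1e-12)


def test_transform_preserves_identity_argmax():
    alleles = ["ACGTACGTGG"] * 3
    pset = consistency_transform(compute_posteriors(alleles, PARAMS), n_rounds=2)
    m = np.asarray(pset.get(0, 1))
    assert np.array_equal(m.argmax(axis=1), np.arange(len(alleles[0])))


def test_identical_alleles_confident_columns():
    msa = align_bubble(["ACGTACGTGGAT"] * 5, CFG)
    assert np.all(msa.confidence >= 0.99)
    assert segment_variants(msa, 0.99) == []


def test_gap_columns_have_defined_confidence():
    msa = align_bubble(["A" * 10, "A" * 60], CFG)
    assert msa.n_columns >= 60
    assert not np.any(np.isnan(msa.confidence))
    assert msa.ungapped(0) == "A" * 10 and msa.ungapped(1) == "A" * 60


def test_ungapping_invariance_random():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ACGT"), 80))
    alleles = [base]
    for _ in range(3):
        a = list(base)
        for pos in rng.choice(80, size=4, replace=False):
            a[int(pos)] = "ACGT"[int(rng.integers(4))]
        alleles.append("".join(a))
    pset = consistency_transform(compute_posteriors(alleles, PARAMS))
    msa = progressive_align(alleles, pset)
    for r, a in enumerate(alleles):
        assert msa.ungapped(r) == a


def test_snp_bubble_single_tight_locus():
    msa = align_bubble(["AAAACAAAAA", "AAAATAAAAA", "AAAACAAAAA"], CFG)
    loci = segment_variants(msa, CFG.column_conf_threshold)
    assert len(loci) == 1
    s, e, alleles = loci[0]
    assert {len(a) for a in alleles} == {e - s}


def test_fully_gapped_low_confidence_run():
    # one internal low-confidence run, fully gapped in all but the last row
    rows = ["AAAA" + "-" * 120 + "TTTT"] * 4 + ["AAAA" + "G" * 120 + "TTTT"]
    conf = np.concatenate([np.ones(4), np.zeros(120), np.ones(4)])
    loci = segment_variants(MsaWithConfidence(rows=rows, confidence=conf), 0.99)
    assert len(loci) == 1
    _, _, alleles = loci[0]
    assert sorted(len(a) for a in alleles) == [0, 0, 0, 0, 120]


def test_threshold_monotonicity():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list("ACGT"), 120))
    a1 = base[:40] + base[46:]
    a2 = base[:90] + "TTTTTT" + base[90:]
    msa = align_bubble([base, a1, a2], CFG)
    lo = segment_variants(msa, 0.95)
    hi = segment_variants(msa, 0.99)
    for s, e, _ in lo:
        assert any(hs <= s and e <= he for hs, he, _ in hi)


def test_block_fallback_single_locus():
    big = ["A" * 3000, "A" * 2500]
    msa = align_bubble(big, CFG)
    assert float(msa.confidence.max()) == 0.0
    assert msa.ungapped(0) == big[0] and msa.ungapped(1) == big[1]
    loci = segment_variants(msa, CFG.column_conf_threshold)
    assert len(loci) == 1
    assert sorted(len(a) for a in loci[0][2]) == [2500, 3000]


def test_single_allele_trivial_msa():
    msa = progressive_align(["ACGT"], compute_posteriors(["ACGT"], PARAMS))
    assert msa.rows == ["ACGT"]
    assert np.all(msa.confidence == 1.0)
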