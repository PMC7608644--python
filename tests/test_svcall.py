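"""SV definition, uniqueness flags, reference-based subset, set comparisons."""

from __future__ import annotations

import pytest

from svscape.callset import (
    define_svs,
    flag_unique,
    nonreciprocal_overlap,
    reference_based_subset,
    venn_counts,
)
from svscape.config import PipelineConfig
from svscape.core import SvLocus, VariantLocus

CFG = PipelineConfig()


def _locus(lengths, spanned=None, chrom="chr", start=0):
    alleles = ["A" * l for l in lengths]
    if spanned is None:
        spanned = tuple(True for _ in lengths)
    return VariantLocus(
        chrom=chrom, start=start, end=start + lengths[0], alleles=alleles, spanned=spanned
    )


def _sv(lengths, spanned=None, **kw):
    alleles = ["A" * l for l in lengths]
    if spanned is None:
        spanned = tuple(True for _ in lengths)
    return SvLocus(
        chrom=kw.pop("chrom", "chr"),
        start=kw.pop("start", 0),
        end=kw.pop("end", lengths[0]),
        alleles=alleles,
        spanned=spanned,
        is_sv=True,
        **kw,
    )


def test_threshold_boundary_exact():
    hit = define_svs([_locus([100, 150])], CFG)[0]
    miss = define_svs([_locus([100, 149])], CFG)[0]
    assert hit.is_sv and not miss.is_sv


def test_unspanned_alleles_excluded_from_range():
    # the 200 bp allele is unspanned: range over spanned alleles is 0
    locus = _locus([100, 100, 200], spanned=(True, True, False))
    sv = define_svs([locus], CFG)[0]
    assert not sv.is_sv and not sv.fully_assessed
    # spanned long allele flips the call
    sv2 = define_svs([_locus([100, 100, 200])], CFG)[0]
    assert sv2.is_sv and sv2.fully_assessed


def test_flag_unique_cases():
    assert flag_unique(_sv([100, 105, 110, 100, 200]), CFG) == 4
    assert flag_unique(_sv([100, 100, 175, 175, 250]), CFG) is None
    assert flag_unique(_sv([100, 160, 100, 100, 100]), CFG) == 1
    # two haplotypes qualify individually -> ambiguous -> None
    assert flag_unique(_sv([100, 160, 160, 160, 160]), CFG) == 0


def test_unique_flag_set_by_define_svs():
    sv = define_svs([_locus([100, 105, 110, 100, 200])], CFG)[0]
    assert sv.unique_to == 4
    # not fully assessed: no uniqueness flag even when an SV
    locus = _locus([100, 105, 110, 100, 200], spanned=(True, True, True, True, False))
    assert define_svs([locus], CFG)[0].unique_to is None


def test_reference_based_subset_examples():
    kept = _sv([100, 250, 100])  # hap1 differs by 150 from reference
    boundary = _sv([100, 150, 120])  # exactly 50 -> kept
    dropped = _sv([100, 120, 140])  # SV (range 40+... actually range 40)
    # a multi-allelic SV invisible against the reference: non-reference
    # alleles differ from each other but each is <50 from the reference
    invisible = _sv([100, 140, 60])
    subset = reference_based_subset([kept, boundary, dropped, invisible], CFG)
    assert kept in subset and boundary in subset
    assert dropped not in subset and invisible not in subset


def test_venn_partition_identity():
    svs = [
        _sv([100, 200, 100, 100, 100]),
        _sv([100, 200, 200, 100, 100]),
        _sv([100, 200, 200, 200, 200]),
        _sv([100, 100, 100, 100, 300]),
        _sv([100, 200, 100, 200, 100]),
    ]
    ref_based = reference_based_subset(svs, CFG)
    counts = venn_counts(ref_based, CFG)
    assert sum(counts.values()) == len(ref_based) == 5
    assert counts[(1,)] == 1
    assert counts[(1, 2)] == 1
    assert counts[(1, 3)] == 1
    assert counts[(4,)] == 1
    assert counts[(1, 2, 3, 4)] == 1
    assert set(counts) == {
        s
        for k in range(1, 5)
        for s in __import__("itertools").combinations((1, 2, 3, 4), k)
    }


def test_overlap_examples():
    flags, counts = nonreciprocal_overlap(
        [("chr", 100, 200), ("chr", 200, 300)], [("chr", 199, 300)]
    )
    assert flags == [True, True]
    flags, _ = nonreciprocal_overlap([("chr", 100, 199)], [("chr", 199, 300)])
    assert flags == [False]  # half-open: touching intervals do not overlap
    flags, counts = nonreciprocal_overlap(
        [("chr", 0, 100)], [("chr", 0, 40)], reciprocal=0.5
    )
    assert flags == [False] and counts == {"matched": 0, "unmatched": 1}
    flags, _ = nonreciprocal_overlap([("chr", 0, 100)], [("chr", 0, 60)], reciprocal=0.5)
    assert flags == [True]


def test_overlap_insertion_points_and_chromosomes():
    # zero-length insertion point still matches an enclosing interval
    flags, _ = nonreciprocal_overlap([("chr", 50, 50)], [("chr", 0, 100)])
    assert flags == [True]
    flags, _ = nonreciprocal_overlap([("chrX", 0, 100)], [("chr", 0, 100)])
    assert flags == [False]


def test_overlap_malformed_interval_errors():
    with pytest.raises(ValueError, match="malformed"):
        nonreciprocal_overlap([("chr", 200, 100)], [])
    with pytest.raises(ValueError, match="malformed"):
        nonreciprocal_overlap([("chr", 100)], [])


def test_overlap_permutation_invariance():
    import random

    a = [("chr", i * 50, i * 50 + 40) for i in range(20)]
    b = [("chr", 100, 400), ("chr", 700, 705)]
    flags, counts = nonreciprocal_overlap(a, b)
    rng = random.Random(0)
    for _ in range(3):
        perm = list(range(len(a)))
        rng.shuffle(perm)
        f2, c2 = nonreciprocal_overlap([a[p] for p in perm], b)
        assert [f2[perm.index(i)] for i in range(len(a))] == flags
        assert c2 == counts
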