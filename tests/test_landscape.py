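"""Regions, subtelomere partition, enrichment, expansion bias, correlations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from svscape.config import ChromosomeSpec, PipelineConfig
from svscape.core import Region, SvClass, SvLocus, TandemRepeat, karyotype_table
from svscape.landscape import (
    assign_regions,
    expansion_matrix,
    fold_enrichment,
    gene_vntr_correlation,
    spearman,
    subtelomere_partition,
    vntr_density_track,
)

CFG = PipelineConfig()


def _sv(lengths, chrom="a", start=0, end=None, svclass=SvClass.UNCLASSIFIED, repeat=None):
    return SvLocus(
        chrom=chrom,
        start=start,
        end=start + (lengths[0] if end is None else end - start),
        alleles=["A" * l for l in lengths],
        spanned=(True,) * len(lengths),
        is_sv=True,
        svclass=svclass,
        repeat=repeat,
    )


def _gene_models():
    # one gene [1001, 5000] 1-based with a CDS [2001, 2500] and UTR [1001, 1200]
    return pd.DataFrame(
        [
            ("a", "sim", "gene", 1001, 5000, ".", "+", ".", "ID=g1"),
            ("a", "sim", "five_prime_UTR", 1001, 1200, ".", "+", ".", "Parent=g1"),
            ("a", "sim", "CDS", 2001, 2500, ".", "+", ".", "Parent=g1"),
        ],
        columns=[
            "seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes",
        ],
    )


def test_region_precedence_and_insertion_point():
    gm = _gene_models()
    cds = _sv([100], start=2100)      # inside CDS
    both = _sv([2000], start=500, end=2500)  # spans UTR + CDS: CDS wins
    utr = _sv([50], start=1050)
    intron = _sv([100], start=3000)
    outside = _sv([100], start=8000)
    insertion = _sv([0, 200], start=2200, end=2200)  # zero reference footprint
    svs = [cds, both, utr, intron, outside, insertion]
    assign_regions(svs, gm)
    assert cds.region is Region.CDS and both.region is Region.CDS
    assert utr.region is Region.UTR and intron.region is Region.INTRON
    assert outside.region is Region.INTERGENIC
    assert insertion.region is Region.CDS  # insertion point rule


def test_partition_geometry():
    karyo = karyotype_table(
        [
            ChromosomeSpec("a", 10_000_000, 4_000_000),
            ChromosomeSpec("b", 10_000_000, 4_000_000, acrocentric_p=True),
        ]
    )
    part = subtelomere_partition(karyo, 1_000_000)
    assert part.subtelomere["a"] == [(0, 1_000_000), (9_000_000, 10_000_000)]
    assert part.subtelomere["b"] == [(9_000_000, 10_000_000)]
    assert part.mb_in() == pytest.approx(3.0)
    assert part.mb_out() == pytest.approx(17.0)
    assert part.is_subtelomeric("a", 999_999)
    assert not part.is_subtelomeric("a", 1_000_000)
    # span 0: nothing subtelomeric
    assert subtelomere_partition(karyo, 0).mb_in() == 0.0
    with pytest.raises(ValueError):
        subtelomere_partition(karyo, 20_000_000)


def test_partition_exclusion_changes_density_not_counts():
    karyo = karyotype_table([ChromosomeSpec("a", 10_000_000, 4_000_000)])
    svs = [_sv([100], start=500_000 + i * 10_000) for i in range(10)]
    svs += [_sv([100], start=5_000_000 + i * 10_000) for i in range(10)]
    base = subtelomere_partition(karyo, 1_000_000)
    # exclude 1 Mb of non-subtelomeric, SV-free sequence
    excl = subtelomere_partition(
        karyo, 1_000_000, exclusion={"a": [(7_000_000, 8_000_000)]}
    )
    r1 = fold_enrichment(svs, base, n_permutations=0)
    r2 = fold_enrichment(svs, excl, n_permutations=0)
    assert (r1.count_in, r1.count_out) == (r2.count_in, r2.count_out) == (10, 10)
    assert r2.mb_out == r1.mb_out - 1.0
    assert r2.fold < r1.fold  # denser outside after exclusion


def test_enrichment_gc_and_pattern_filters_are_strict():
    karyo = karyotype_table([ChromosomeSpec("a", 10_000_000, 4_000_000)])
    part = subtelomere_partition(karyo, 1_000_000)

    def vntr(start, gc, period):
        rep = TandemRepeat(
            period=period, consensus="G" * period, copies=5.0, score=50,
            gc=gc, entropy=1.0, span_fraction=0.9,
        )
        return _sv([100], start=start, svclass=SvClass.VNTR, repeat=rep)

    svs = [
        vntr(100, gc=0.60, period=30),   # GC exactly at the bound: excluded
        vntr(200, gc=0.61, period=20),   # period exactly at the bound: excluded
        vntr(300, gc=0.61, period=21),   # kept
        _sv([100], start=400, svclass=SvClass.OTHER),  # wrong class
    ]
    res = fold_enrichment(svs, part, sv_filter=(0.6, 20), n_permutations=0)
    assert res.total == 1 and res.count_in == 1


def test_enrichment_class_filter_and_uniform_sanity():
    karyo = karyotype_table([ChromosomeSpec("a", 10_000_000, 4_000_000)])
    part = subtelomere_partition(karyo, 1_000_000)
    rng = np.random.default_rng(0)
    svs = [
        _sv([100], start=int(p), svclass=SvClass.VNTR)
        for p in rng.integers(0, 10_000_000, size=400)
    ]
    res = fold_enrichment(svs, part, classes={SvClass.VNTR}, seed=1)
    assert res.total == 400
    assert res.fold == pytest.approx(1.0, abs=0.5)
    assert res.p_value > 0.025
    # empty selection
    empty = fold_enrichment(svs, part, classes={SvClass.MEI})
    assert empty.total == 0 and empty.p_value is None


def test_expansion_matrix_counts_and_transpose():
    svs = [_sv([100, 100, 100, 100, 200])] * 4 + [_sv([300, 100, 100, 100, 100])]
    m = expansion_matrix(svs, threshold=50)
    k = 5
    assert m.smaller.shape == (k, k)
    # haplotype 4 is larger than every other in 4 loci
    assert all(m.smaller[x, 4] == 4 for x in range(4))
    # at the fifth locus only haplotype 0 carries the long allele
    assert all(m.smaller[x, 0] == 1 for x in range(1, 5))
    assert m.smaller[4, 1] == 0 and m.smaller[1, 2] == 0
    assert np.array_equal(m.larger, m.smaller.T)
    assert np.all(np.diag(m.smaller) == 0)
    assert m.z_scores.shape == (k, len(svs))
    assert np.allclose(m.z_scores.sum(axis=0), 0.0)


def test_expansion_matrix_constant_locus_asserts():
    with pytest.raises(AssertionError):
        expansion_matrix([_sv([100, 100, 100])])


def _brute_spearman(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def test_spearman_matches_rank_pearson_and_guards():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.integers(0, 8, size=30).astype(float)  # heavy ties
        y = rng.normal(size=30)
        r, p = spearman(x, y)
        assert r == pytest.approx(_brute_spearman(x, y), abs=1e-12)
        assert 0.0 <= p <= 1.0
    r, p = spearman([1.0] * 10, list(range(10)))
    assert math.isnan(r) and math.isnan(p)


def test_gene_vntr_correlation_counts_and_exclusion():
    gm = pd.DataFrame(
        [
            ("a", "sim", "gene", 1001, 3000, ".", "+", ".", "ID=g1"),
            ("a", "sim", "gene", 10_001, 30_000, ".", "+", ".", "ID=g2"),
            ("a", "sim", "gene", 50_001, 90_000, ".", "+", ".", "ID=g3"),
        ],
        columns=[
            "seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes",
        ],
    )
    expression = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "brain_a": [1.0, 100.0], "liver": [5.0, 5.0]}
    )
    svs = [
        _sv([100], start=1_500, svclass=SvClass.VNTR),
        _sv([100], start=15_000, svclass=SvClass.VNTR),
        _sv([100], start=20_000, svclass=SvClass.VNTR),
        _sv([100], start=15_500, svclass=SvClass.OTHER),  # not counted
    ]
    res = gene_vntr_correlation(svs, gm, expression, ["brain_a"])
    assert res.excluded == ["g3"] and res.n_genes == 2
    counts = dict(zip(res.table["gene_id"], res.table["vntr_count"]))
    assert counts == {"g1": 1, "g2": 2}
    # two genes, longer gene more VNTRs and higher expression: r = 1
    assert res.r_length == pytest.approx(1.0) and res.r_vntr == pytest.approx(1.0)
    with pytest.raises(ValueError, match="brain regions absent"):
        gene_vntr_correlation(svs, gm, expression, ["brain_missing"])


def test_vntr_density_track_bins():
    ref = {"a": "ACGT" * 75_000}  # 300 kb
    svs = [
        _sv([100], start=50_000, svclass=SvClass.VNTR),
        _sv([100], start=250_000, svclass=SvClass.VNTR),
        _sv([100], start=250_500, svclass=SvClass.OTHER),
    ]
    track = vntr_density_track(svs, ref, bin_size=100_000)
    assert list(track["vntr_count"]) == [1, 0, 1]
    assert all(track["gc"] == 0.5)
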