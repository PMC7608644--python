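"""Synthetic genome generator: determinism, truth bookkeeping, gene models."""

from __future__ import annotations

import numpy as np
import pytest

from svscape.config import ChromosomeSpec, GeneParams, SimulationConfig
from svscape.core import (
    VariantClass,
    karyotype_table,
    revcomp,
    subtelomere_intervals,
)
from svscape.landscape import spearman
from svscape.simulate import (
    generate_gene_models_and_expression,
    generate_reference,
    plant_variants,
    simulate,
)


def _small_config(**kw) -> SimulationConfig:
    base = dict(
        seed=7,
        chromosomes=(ChromosomeSpec("chr1", 300_000, 140_000),),
        subtelomere_span=20_000,
        n_vntr=6,
        n_mei=3,
        n_del=2,
        n_inv=2,
        n_subthreshold=1,
        gene=GeneParams(n_genes=20, length_range=(2_000, 10_000)),
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_reference_deterministic_and_sized():
    cfg = _small_config()
    ref1, karyo1 = generate_reference(cfg)
    ref2, _ = generate_reference(cfg)
    assert ref1.seqs[0] == ref2.seqs[0]
    assert len(ref1.seqs[0]["chr1"]) == 300_000
    ref3, _ = generate_reference(_small_config(seed=8))
    assert ref3.seqs[0] != ref1.seqs[0]
    assert set(karyo1["arm"]) == {"p", "q"}


def test_reference_too_short_errors():
    # subtelomere span exceeding the shortest arm is rejected up front
    with pytest.raises(ValueError, match="exceeds the shortest arm"):
        _small_config(
            chromosomes=(ChromosomeSpec("chr1", 30_000, 14_000),),
            subtelomere_span=20_000,
        )


def test_subtelomere_mask_definition_and_acrocentric():
    karyo = karyotype_table(
        [
            ChromosomeSpec("a", 1_000_000, 400_000),
            ChromosomeSpec("b", 1_000_000, 400_000, acrocentric_p=True),
        ]
    )
    mask = subtelomere_intervals(karyo, 100_000)
    assert mask["a"] == [(0, 100_000), (900_000, 1_000_000)]
    # acrocentric p-arm: only the q-terminal block is masked
    assert mask["b"] == [(900_000, 1_000_000)]
    assert subtelomere_intervals(karyo, 0) == {"a": [], "b": []}
    with pytest.raises(ValueError):
        subtelomere_intervals(karyo, 2_000_000)


def test_truth_lengths_match_sequence_extraction():
    cfg = _small_config()
    plant, _ = simulate(cfg)
    assert len(plant.truth) == cfg.total_planted
    for t, intervals in zip(plant.truth, plant.allele_intervals):
        for h, (s, e) in enumerate(intervals):
            extracted = plant.assembly.seqs[h][t.chrom][s:e]
            assert len(extracted) == t.allele_lengths[h]
        if t.vclass is VariantClass.INV:
            # carriers hold the reverse complement of the reference window
            ref_s, ref_e = intervals[0]
            window = plant.assembly.seqs[0][t.chrom][ref_s:ref_e]
            carried = {
                plant.assembly.seqs[h][t.chrom][s:e]
                for h, (s, e) in enumerate(intervals[1:], start=1)
            }
            assert carried <= {window, revcomp(window)}


def test_planted_ranges_respect_sv_threshold():
    plant, _ = simulate(_small_config())
    for t in plant.truth:
        if t.vclass is VariantClass.INV:
            assert t.length_range == 0  # balanced by construction
        elif t.sub_threshold:
            assert 0 < t.length_range < 50
        else:
            assert t.length_range >= 50


def test_vntr_copy_arithmetic():
    plant, _ = simulate(_small_config())
    vntrs = [t for t in plant.truth if t.vclass is VariantClass.VNTR]
    assert vntrs
    for t in vntrs:
        unit = len(t.subunit)
        assert all(l % unit == 0 for l in t.allele_lengths)
        assert len(set(t.subunit)) >= 2  # never a homopolymer


def test_gene_models_empty_and_monotone():
    cfg = _small_config(gene=GeneParams(n_genes=0))
    karyo = karyotype_table(cfg.chromosomes)
    features, expression = generate_gene_models_and_expression(cfg, karyo)
    assert features.empty and expression.empty
    assert "gene_id" in expression.columns

    import dataclasses

    cfg2 = _small_config(
        chromosomes=(ChromosomeSpec("chr1", 3_000_000, 1_400_000),),
        gene=GeneParams(n_genes=80, length_range=(2_000, 20_000)),
    )
    cfg2 = dataclasses.replace(
        cfg2, expression=dataclasses.replace(cfg2.expression, length_correlation=1.0)
    )
    features, expression = generate_gene_models_and_expression(
        cfg2, karyotype_table(cfg2.chromosomes)
    )
    genes = features[features["type"] == "gene"]
    lengths = (genes["end"].astype(int) - genes["start"].astype(int) + 1).to_numpy()
    brain = list(cfg2.expression.brain_regions)
    tpm = expression[brain].mean(axis=1).to_numpy()
    r, _ = spearman(lengths, np.log10(tpm + 1e-3))
    assert r == pytest.approx(1.0, abs=1e-12)


def test_gene_features_are_consistent():
    cfg = _small_config()
    features, expression = generate_gene_models_and_expression(
        cfg, karyotype_table(cfg.chromosomes)
    )
    genes = features[features["type"] == "gene"]
    assert len(genes) == cfg.gene.n_genes
    assert set(expression["gene_id"]) == {
        a.split("=", 1)[1] for a in genes["attributes"]
    }
    # exons = CDS + UTR inside each gene; all features within the gene body
    for _, g in genes.iterrows():
        sub = features[
            features["attributes"].str.contains(g["attributes"].split("=")[1])
        ]
        assert int(sub["start"].min()) >= int(g["start"])
        assert int(sub["end"].max()) <= int(g["end"])


def test_bad_correlation_rejected():
    import dataclasses

    cfg = _small_config()
    with pytest.raises(ValueError):
        dataclasses.replace(
            cfg, expression=dataclasses.replace(cfg.expression, length_correlation=1.5)
        )


def test_plant_determinism():
    cfg = _small_config()
    a, _ = simulate(cfg)
    b, _ = simulate(cfg)
    assert a.assembly.seqs == b.assembly.seqs
    assert a.truth == b.truth
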