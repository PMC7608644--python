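"""End-to-end orchestration: simulate -> anchor -> align -> call ->
classify -> rearrange -> landscape, with a run manifest (config echo,
seeds, stage timings, output digests) and a logged summary block.

All stochastic behavior flows from the single simulation seed; rerunning
with the same configs reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from svscape import io as svio
from svscape.anchors import anchor_assembly
from svscape.callset import (
    compendium_table,
    define_svs,
    reference_based_subset,
    venn_counts,
)
from svscape.config import PipelineConfig, SimulationConfig
from svscape.core import (
    Bubble,
    InversionCall,
    SvClass,
    SvLocus,
    TruthRecord,
    chromosome_lengths,
)
from svscape.landscape import (
    EnrichmentResult,
    ExpansionMatrix,
    GenomePartition,
    GeneVntrResult,
    assign_regions,
    expansion_matrix,
    flag_subtelomeric,
    fold_enrichment,
    gene_vntr_correlation,
    subtelomere_partition,
)
from svscape.msa import bubble_to_loci
from svscape.rearrange import (
    build_breakpoint_graph,
    call_inversions,
    chain_segments,
    segments_bed,
)
from svscape.repeats import classify_all, reference_repeat_track
from svscape.simulate import (
    generate_gene_models_and_expression,
    mei_library,
    simulate,
)

logger = logging.getLogger("svscape")


@dataclass
class RunManifest:
    seed: int
    sim_config: dict
    pipe_config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    assembly: object
    karyotype: pd.DataFrame
    truth: list[TruthRecord]
    bubbles: list[Bubble]
    loci: list
    svs: list[SvLocus]
    inversions: dict[int, list[InversionCall]]
    segments: dict[int, list]
    breakpoint_gfa: str
    partition: GenomePartition
    enrichment: dict[str, EnrichmentResult]
    expansion: ExpansionMatrix
    gene_models: pd.DataFrame
    expression: pd.DataFrame
    gene_stats: GeneVntrResult
    venn: dict
    manifest: RunManifest


def _config_dict(cfg) -> dict:
    def clean(v):
        if dataclasses.is_dataclass(v):
            return {f.name: clean(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if hasattr(v, "tolist"):  # numpy arrays and scalars
            return v.tolist()
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return clean(cfg)


def run_pipeline(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    cfg = pipe_config or PipelineConfig()
    manifest = RunManifest(
        seed=sim_config.seed,
        sim_config=_config_dict(sim_config),
        pipe_config=_config_dict(cfg),
    )
    timings = manifest.stage_seconds

    t0 = time.time()
    plant, karyotype = simulate(sim_config)
    gene_models, expression = generate_gene_models_and_expression(
        sim_config, karyotype
    )
    if expression.empty and sim_config.gene.n_genes > 0:
        raise RuntimeError("stage simulate: expression table empty")
    assembly, truth = plant.assembly, plant.truth
    timings["simulate"] = round(time.time() - t0, 3)

    t0 = time.time()
    anchored = anchor_assembly(
        assembly, cfg.min_anchor_length, cfg.bubble_align_cap
    )
    bubbles = [b for _, (_, bs) in sorted(anchored.items()) for b in bs]
    timings["anchor"] = round(time.time() - t0, 3)

    t0 = time.time()
    loci = []
    for b in bubbles:
        loci.extend(bubble_to_loci(b, cfg))
    timings["align"] = round(time.time() - t0, 3)

    t0 = time.time()
    svs = define_svs(loci, cfg)
    sv_set = [s for s in svs if s.is_sv]
    ref_based = reference_based_subset(sv_set, cfg)
    venn = venn_counts(ref_based, cfg)
    timings["call"] = round(time.time() - t0, 3)

    t0 = time.time()
    library = mei_library(sim_config)
    reference = assembly.seqs[0]
    trf_track = reference_repeat_track(reference, sv_set, cfg)
    fractions = classify_all(svs, library, trf_track, cfg)
    timings["classify"] = round(time.time() - t0, 3)

    t0 = time.time()
    vntr_intervals = [
        (s.chrom, s.start, max(s.end, s.start + 1))
        for s in sv_set
        if s.svclass is SvClass.VNTR
    ]
    segments: dict[int, list] = {}
    inversions: dict[int, list[InversionCall]] = {}
    for h in range(1, assembly.n_haplotypes):
        segs = []
        for chrom in assembly.chromosomes:
            q = assembly.get(h, chrom)
            if not q:
                continue
            segs.extend(
                chain_segments(
                    q, reference[chrom], cfg, query_id=f"{assembly.names[h]}.{chrom}",
                    chrom=chrom,
                )
            )
        segments[h] = segs
        inversions[h] = call_inversions(segs, vntr_intervals)
    by_contig: dict[str, list] = {}
    for segs in segments.values():
        for s in segs:
            by_contig.setdefault(s.query_id, []).append(s)
    _, gfa_text = build_breakpoint_graph(by_contig)
    _flag_inv_associated(sv_set, inversions)
    timings["rearrange"] = round(time.time() - t0, 3)

    t0 = time.time()
    assessable = _assessable_mask(assembly, bubbles, karyotype)
    partition = subtelomere_partition(
        karyotype, sim_config.subtelomere_span, assessable=assessable
    )
    assign_regions(svs, gene_models)
    flag_subtelomeric(svs, partition)
    seed = sim_config.seed
    enrichment = {
        "all_svs": fold_enrichment(sv_set, partition, seed=seed),
        "vntr": fold_enrichment(
            sv_set, partition, classes={SvClass.VNTR}, seed=seed
        ),
        "vntr_gc_pattern": fold_enrichment(
            sv_set,
            partition,
            classes={SvClass.VNTR},
            sv_filter=(cfg.gc_filter, cfg.pattern_len_filter),
            seed=seed,
        ),
    }
    expansion = expansion_matrix(sv_set, cfg.sv_min_span)
    gene_stats = gene_vntr_correlation(
        sv_set, gene_models, expression, sim_config.expression.brain_regions,
        partition,
    )
    timings["landscape"] = round(time.time() - t0, 3)

    manifest.counts = {
        "n_loci": len(loci),
        "n_svs": len(sv_set),
        "n_not_fully_assessed": sum(1 for s in sv_set if not s.fully_assessed),
        "n_reference_based": len(ref_based),
        "class_fractions": {k: round(v, 4) for k, v in fractions.items()},
        "unique_per_haplotype": _unique_counts(sv_set, assembly.n_haplotypes),
        "n_inversion_calls": sum(len(v) for v in inversions.values()),
    }
    _log_summary(manifest.counts)

    result = PipelineResult(
        assembly=assembly,
        karyotype=karyotype,
        truth=truth,
        bubbles=bubbles,
        loci=loci,
        svs=svs,
        inversions=inversions,
        segments=segments,
        breakpoint_gfa=gfa_text,
        partition=partition,
        enrichment=enrichment,
        expansion=expansion,
        gene_models=gene_models,
        expression=expression,
        gene_stats=gene_stats,
        venn=venn,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir), cfg)
    return result


def _unique_counts(svs: Sequence[SvLocus], n_hap: int) -> list[int]:
    counts = [0] * n_hap
    for sv in svs:
        if sv.unique_to is not None:
            counts[sv.unique_to] += 1
    return counts


def _flag_inv_associated(
    svs: Sequence[SvLocus], inversions: dict[int, list[InversionCall]]
) -> None:
    """SVs overlapping an inversion call that are not already VNTR/MEI get
    the INV-associated class."""
    calls = [c for v in inversions.values() for c in v]
    for sv in svs:
        if sv.svclass in (SvClass.VNTR, SvClass.MEI):
            continue
        for c in calls:
            if c.chrom == sv.chrom and c.start < max(sv.end, sv.start + 1) and (
                c.end > sv.start
            ):
                sv.svclass = SvClass.INV_ASSOCIATED
                break


def _assessable_mask(assembly, bubbles: Sequence[Bubble], karyotype) -> dict:
    """Reference intervals spanned by all haplotypes: whole chromosomes
    minus bubbles with an unspanned haplotype (and minus chromosomes absent
    from some haplotype)."""
    lengths = chromosome_lengths(karyotype)
    mask = {}
    for chrom, length in lengths.items():
        if any(not assembly.get(h, chrom) for h in range(assembly.n_haplotypes)):
            mask[chrom] = []
            continue
        holes = sorted(
            (b.ref_start, max(b.ref_end, b.ref_start + 1))
            for b in bubbles
            if b.chrom == chrom and not all(b.spanned)
        )
        ivs, cursor = [], 0
        for s, e in holes:
            if s > cursor:
                ivs.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            ivs.append((cursor, length))
        mask[chrom] = ivs
    return mask


def _log_summary(counts: dict) -> None:
    logger.info("variant loci: %d", counts["n_loci"])
    logger.info(
        "SVs: %d (%d not assessable in all haplotypes; %d reference-detectable)",
        counts["n_svs"],
        counts["n_not_fully_assessed"],
        counts["n_reference_based"],
    )
    for cls, frac in counts["class_fractions"].items():
        logger.info("  %s: %.1f%%", cls, 100 * frac)
    logger.info("unique SVs per haplotype: %s", counts["unique_per_haplotype"])
    logger.info("inversion calls: %d", counts["n_inversion_calls"])


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def write_outputs(
    result: PipelineResult, out_dir: Path, cfg: PipelineConfig
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    assembly = result.assembly
    lengths = chromosome_lengths(result.karyotype)

    comp = compendium_table(result.svs)
    comp.to_csv(out_dir / "compendium.tsv", sep="\t", index=False)

    sv_set = [s for s in result.svs if s.is_sv]
    svio.write_vcf(
        out_dir / "svs.vcf", sv_set, list(assembly.names), assembly.seqs[0], lengths
    )
    (out_dir / "breakpoints.gfa").write_text(result.breakpoint_gfa)

    seg_rows = [s for segs in result.segments.values() for s in segs]
    svio.write_bed(out_dir / "segments.bed", segments_bed(seg_rows))

    inv_rows = [
        {
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "query": c.query_id, "zygosity": c.zygosity,
            "ambiguous": int(c.ambiguous),
        }
        for calls in result.inversions.values()
        for c in calls
    ]
    pd.DataFrame(
        inv_rows, columns=["chrom", "start", "end", "query", "zygosity", "ambiguous"]
    ).to_csv(out_dir / "inversions.tsv", sep="\t", index=False)

    enr_rows = []
    for name, e in result.enrichment.items():
        enr_rows.append(
            {
                "set": name, "count_in": e.count_in, "count_out": e.count_out,
                "mb_in": e.mb_in, "mb_out": e.mb_out,
                "fold": "" if e.fold is None else round(e.fold, 4),
                "p_value": "" if e.p_value is None else e.p_value,
            }
        )
    pd.DataFrame(enr_rows).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    pd.DataFrame(result.expansion.smaller).to_csv(
        out_dir / "expansion_smaller.tsv", sep="\t", index=False
    )
    result.gene_stats.table.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    svio.write_gff3(out_dir / "genes.gff3", result.gene_models)
    result.expression.to_csv(out_dir / "expression.tsv", sep="\t", index=False)

    for name in sorted(p.name for p in out_dir.iterdir() if p.is_file()):
        if name != "manifest.json":
            result.manifest.output_digests[name] = svio.file_digest(out_dir / name)
    (out_dir / "manifest.json").write_text(result.manifest.to_json())
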