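"""From variant loci to the structural-variant compendium.

An SV is a locus whose largest allele is at least 50 bp longer than its
shortest, computed over the haplotypes that span the locus.  Loci unspanned
in any haplotype stay in the compendium but are excluded from the
fully-assessed set.  All thresholds act on allele lengths, never on edit
distance.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from svscape.config import PipelineConfig
from svscape.core import SvLocus, VariantLocus


def define_svs(loci: Iterable[VariantLocus], config: PipelineConfig) -> list[SvLocus]:
    """Promote variant loci to SvLocus records with the multi-allelic SV
    definition applied (length range >= sv_min_span over spanned haplotypes)."""
    out = []
    for locus in loci:
        lens = [
            len(a) for a, sp in zip(locus.alleles, locus.spanned) if sp
        ]
        is_sv = bool(lens) and max(lens) - min(lens) >= config.sv_min_span
        sv = SvLocus(
            chrom=locus.chrom,
            start=locus.start,
            end=locus.end,
            alleles=list(locus.alleles),
            spanned=tuple(locus.spanned),
            is_sv=is_sv,
            fully_assessed=all(locus.spanned),
        )
        if sv.is_sv and sv.fully_assessed:
            sv.unique_to = flag_unique(sv, config)
        out.append(sv)
    return out


def flag_unique(sv: SvLocus, config: PipelineConfig) -> int | None:
    """Leave-one-out uniqueness: haplotype h iff removing h brings the
    length range below the SV threshold; None when no or several haplotypes
    qualify."""
    lens = sv.allele_lengths
    hits = []
    for h in range(len(lens)):
        rest = [l for k, l in enumerate(lens) if k != h]
        if rest and max(rest) - min(rest) < config.sv_min_span:
            hits.append(h)
    return hits[0] if len(hits) == 1 else None


def reference_based_subset(
    svs: Sequence[SvLocus], config: PipelineConfig, ref_index: int = 0
) -> list[SvLocus]:
    """SVs detectable against the reference haplotype: at least one
    non-reference allele differs >= sv_min_span bp in length from the
    reference allele."""
    kept = []
    for sv in svs:
        ref_len = len(sv.alleles[ref_index])
        if any(
            abs(len(a) - ref_len) >= config.sv_min_span
            for h, a in enumerate(sv.alleles)
            if h != ref_index
        ):
            kept.append(sv)
    return kept


def venn_counts(
    reference_based_svs: Sequence[SvLocus],
    config: PipelineConfig,
    ref_index: int = 0,
) -> dict[tuple[int, ...], int]:
    """Membership counts over every non-empty subset of non-reference
    haplotypes; haplotype h is a member at a locus iff its allele length
    differs >= sv_min_span from the reference allele.  The counts partition
    the reference-based set."""
    n = len(reference_based_svs[0].alleles) if reference_based_svs else 0
    non_ref = [h for h in range(n) if h != ref_index]
    counts: dict[tuple[int, ...], int] = {
        subset: 0
        for k in range(1, len(non_ref) + 1)
        for subset in combinations(non_ref, k)
    }
    for sv in reference_based_svs:
        ref_len = len(sv.alleles[ref_index])
        members = tuple(
            h for h in non_ref if abs(len(sv.alleles[h]) - ref_len) >= config.sv_min_span
        )
        counts[members] += 1
    return counts


def _check_intervals(intervals: Sequence[tuple]) -> None:
    for iv in intervals:
        if len(iv) < 3:
            raise ValueError(f"malformed interval {iv!r}: need (chrom, start, end)")
        chrom, start, end = iv[0], iv[1], iv[2]
        if not isinstance(chrom, str) or end < start:
            raise ValueError(f"malformed interval {iv!r}")


def nonreciprocal_overlap(
    set_a: Sequence[tuple],
    set_b: Sequence[tuple],
    reciprocal: float | None = None,
) -> tuple[list[bool], dict[str, int]]:
    """Per-interval match flags for A against B (half-open intervals on the
    same reference).  Default mode: matched iff >= 1 bp overlap with any B
    interval.  With ``reciprocal=f``, a match additionally requires the
    overlap to cover >= f of both intervals."""
    _check_intervals(set_a)
    _check_intervals(set_b)
    # zero-length intervals (insertion points) are widened to 1 bp
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, *_ in set_b:
        trees.setdefault(chrom, IntervalTree()).addi(start, max(end, start + 1))
    flags = []
    for chrom, start, end, *_ in set_a:
        end = max(end, start + 1)
        tree = trees.get(chrom)
        matched = False
        if tree is not None:
            for hit in tree.overlap(start, end):
                ov = min(end, hit.end) - max(start, hit.begin)
                if ov < 1:
                    continue
                if reciprocal is None:
                    matched = True
                    break
                la, lb = max(end - start, 1), max(hit.end - hit.begin, 1)
                if ov / la >= reciprocal and ov / lb >= reciprocal:
                    matched = True
                    break
        flags.append(matched)
    counts = {"matched": sum(flags), "unmatched": len(flags) - sum(flags)}
    return flags, counts


def compendium_table(svs: Sequence[SvLocus]) -> pd.DataFrame:
    """One row per locus: coordinates, per-haplotype lengths, class, repeat
    stats, region, subtelomeric flag (the compendium TSV layout)."""
    rows = []
    for sv in svs:
        rep = sv.repeat
        rows.append(
            {
                "chrom": sv.chrom,
                "start": sv.start,
                "end": sv.end,
                "allele_lengths": ",".join(str(l) for l in sv.allele_lengths),
                "spanned": ",".join("1" if s else "0" for s in sv.spanned),
                "is_sv": int(sv.is_sv),
                "fully_assessed": int(sv.fully_assessed),
                "unique_to": "" if sv.unique_to is None else sv.unique_to,
                "class": sv.svclass.value,
                "mei_family": sv.mei_family or "",
                "repeat_period": rep.period if rep else "",
                "repeat_copies": round(rep.copies, 2) if rep else "",
                "repeat_score": rep.score if rep else "",
                "repeat_gc": round(rep.gc, 3) if rep else "",
                "repeat_entropy": round(rep.entropy, 3) if rep else "",
                "repeat_bin": rep.consensus_bin if rep else "",
                "region": sv.region.value if sv.region else "",
                "subtelomeric": int(sv.subtelomeric),
            }
        )
    return pd.DataFrame(rows)
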