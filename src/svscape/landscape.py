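"""Genomic-context annotation and landscape statistics.

Covers region assignment (CDS > UTR > intron > intergenic precedence,
insertion-point rule for pure insertions), the subtelomeric partition with
assessable-Mb denominators, fold enrichment with a seeded permutation
p-value, expansion-bias count matrices with per-haplotype z-score profiles,
and the gene-level VNTR-vs-expression correlations (Spearman, average ranks
on ties, t-approximation p-values via scipy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from svscape.config import PipelineConfig
from svscape.core import Region, SvClass, SvLocus, subtelomere_intervals

LOG_OFFSET = 1e-3  # TPM offset before log10 (expression tables contain zeros)


# --------------------------------------------------------------------------
# region assignment
# --------------------------------------------------------------------------


def _feature_trees(gene_models: pd.DataFrame) -> dict[str, dict[str, IntervalTree]]:
    """Interval trees (0-based half-open) per chromosome for CDS, UTR and
    gene bodies, from 1-based inclusive GFF3-style rows."""
    trees: dict[str, dict[str, IntervalTree]] = {"CDS": {}, "UTR": {}, "gene": {}}
    kind_of = {
        "CDS": "CDS",
        "five_prime_UTR": "UTR",
        "three_prime_UTR": "UTR",
        "gene": "gene",
    }
    for row in gene_models.itertuples(index=False):
        kind = kind_of.get(row.type)
        if kind is None:
            continue
        chrom = row.seqid
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        name = attrs.get("ID") or attrs.get("Parent") or ""
        trees[kind].setdefault(chrom, IntervalTree()).addi(
            int(row.start) - 1, int(row.end), name
        )
    return trees


def assign_region(
    sv: SvLocus, trees: dict[str, dict[str, IntervalTree]]
) -> Region:
    """Highest-precedence region overlapped by the SV's reference interval;
    a zero-length reference footprint (pure insertion) uses its insertion
    point."""
    start, end = sv.start, max(sv.end, sv.start + 1)
    for kind, region in (("CDS", Region.CDS), ("UTR", Region.UTR)):
        tree = trees[kind].get(sv.chrom)
        if tree is not None and tree.overlap(start, end):
            return region
    tree = trees["gene"].get(sv.chrom)
    if tree is not None and tree.overlap(start, end):
        return Region.INTRON
    return Region.INTERGENIC


def assign_regions(svs: Sequence[SvLocus], gene_models: pd.DataFrame) -> None:
    trees = _feature_trees(gene_models)
    for sv in svs:
        sv.region = assign_region(sv, trees)


# --------------------------------------------------------------------------
# partition and enrichment
# --------------------------------------------------------------------------


def _interval_len(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in ivs)


def _intersect(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return sorted(out)


def _subtract(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in sorted(a):
        cur = s
        for s2, e2 in sorted(b):
            if e2 <= cur or s2 >= e:
                continue
            if s2 > cur:
                out.append((cur, s2))
            cur = max(cur, e2)
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class GenomePartition:
    """Subtelomere and assessable masks over the reference."""

    chrom_lengths: dict[str, int]
    subtelomere: dict[str, list[tuple[int, int]]]
    assessable: dict[str, list[tuple[int, int]]]

    @property
    def assessable_in(self) -> dict[str, list[tuple[int, int]]]:
        return {
            c: _intersect(self.assessable.get(c, []), self.subtelomere.get(c, []))
            for c in self.chrom_lengths
        }

    @property
    def assessable_out(self) -> dict[str, list[tuple[int, int]]]:
        return {
            c: _subtract(self.assessable.get(c, []), self.subtelomere.get(c, []))
            for c in self.chrom_lengths
        }

    def mb_in(self) -> float:
        return sum(_interval_len(v) for v in self.assessable_in.values()) / 1e6

    def mb_out(self) -> float:
        return sum(_interval_len(v) for v in self.assessable_out.values()) / 1e6

    def is_subtelomeric(self, chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.subtelomere.get(chrom, []))


def subtelomere_partition(
    karyotype: pd.DataFrame,
    span: int,
    assessable: dict[str, list[tuple[int, int]]] | None = None,
    exclusion: dict[str, list[tuple[int, int]]] | None = None,
) -> GenomePartition:
    """Mask the terminal ``span`` bp of every non-acrocentric arm; the
    assessable mask defaults to whole chromosomes, minus the optional
    exclusion intervals.  span greater than a chromosome length errors."""
    from svscape.core import chromosome_lengths

    lengths = chromosome_lengths(karyotype)
    subtel = subtelomere_intervals(karyotype, span)
    if assessable is None:
        assessable = {c: [(0, l)] for c, l in lengths.items()}
    if exclusion:
        assessable = {
            c: _subtract(assessable.get(c, []), exclusion.get(c, []))
            for c in lengths
        }
    return GenomePartition(
        chrom_lengths=lengths, subtelomere=subtel, assessable=assessable
    )


def flag_subtelomeric(svs: Sequence[SvLocus], partition: GenomePartition) -> None:
    for sv in svs:
        sv.subtelomeric = partition.is_subtelomeric(sv.chrom, sv.start)


@dataclass
class EnrichmentResult:
    count_in: int
    count_out: int
    mb_in: float
    mb_out: float
    density_in: float | None
    density_out: float | None
    fold: float | None
    p_value: float | None
    n_permutations: int = 0

    @property
    def total(self) -> int:
        return self.count_in + self.count_out


def fold_enrichment(
    svs: Sequence[SvLocus],
    partition: GenomePartition,
    sv_filter: tuple[float, int] | None = None,
    classes: set[SvClass] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Subtelomeric density fold over assessable Mb.  ``sv_filter=(gc_min,
    pattern_min)`` keeps only VNTRs with repeat GC strictly above gc_min and
    period strictly above pattern_min.  The p-value shuffles SV positions
    uniformly over the assessable mask (seeded)."""
    selected = []
    for sv in svs:
        if classes is not None and sv.svclass not in classes:
            continue
        if sv_filter is not None:
            gc_min, pattern_min = sv_filter
            rep = sv.repeat
            if rep is None or not (rep.gc > gc_min and rep.period > pattern_min):
                continue
        selected.append(sv)
    mb_in, mb_out = partition.mb_in(), partition.mb_out()
    count_in = sum(
        1 for sv in selected if partition.is_subtelomeric(sv.chrom, sv.start)
    )
    count_out = len(selected) - count_in
    if mb_in == 0.0 or mb_out == 0.0:
        return EnrichmentResult(
            count_in, count_out, mb_in, mb_out, None, None, None, None
        )
    d_in, d_out = count_in / mb_in, count_out / mb_out
    fold = d_in / d_out if d_out > 0 else float("inf") if d_in > 0 else None
    p_value = None
    if n_permutations > 0 and selected and fold is not None:
        # flattened assessable mask with an is-subtelomeric flag per segment
        segs = []
        for c in partition.chrom_lengths:
            for s, e in partition.assessable_in[c]:
                segs.append((e - s, True))
            for s, e in partition.assessable_out[c]:
                segs.append((e - s, False))
        weights = np.array([l for l, _ in segs], dtype=float)
        flags = np.array([f for _, f in segs])
        p_sub = weights[flags].sum() / weights.sum()
        rng = np.random.default_rng(seed)
        n = len(selected)
        hits = rng.binomial(n, p_sub, size=n_permutations)
        perm_folds = np.where(
            (n - hits) > 0,
            (hits / mb_in) / np.maximum((n - hits), 1e-12) * mb_out,
            np.inf,
        )
        p_value = float((np.sum(perm_folds >= fold) + 1) / (n_permutations + 1))
    return EnrichmentResult(
        count_in, count_out, mb_in, mb_out, d_in, d_out,
        None if fold is None else float(fold), p_value, n_permutations,
    )


# --------------------------------------------------------------------------
# expansion bias
# --------------------------------------------------------------------------


@dataclass
class ExpansionMatrix:
    smaller: np.ndarray  # cell (x, y): SVs where allele_x <= allele_y - threshold
    z_scores: np.ndarray  # haplotypes x SVs

    @property
    def larger(self) -> np.ndarray:
        return self.smaller.T


def expansion_matrix(svs: Sequence[SvLocus], threshold: int = 50) -> ExpansionMatrix:
    """Pairwise smaller-than counts and per-haplotype z-score series over
    the fully-assessed SV set."""
    use = [sv for sv in svs if sv.is_sv and sv.fully_assessed]
    if not use:
        return ExpansionMatrix(np.zeros((0, 0), dtype=np.int64), np.zeros((0, 0)))
    lens = np.array([sv.allele_lengths for sv in use], dtype=float)  # SVs x K
    k = lens.shape[1]
    smaller = np.zeros((k, k), dtype=np.int64)
    for x in range(k):
        for y in range(k):
            if x != y:
                smaller[x, y] = int(np.sum(lens[:, x] <= lens[:, y] - threshold))
    mean = lens.mean(axis=1, keepdims=True)
    sd = lens.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise AssertionError("zero allele-length s.d. at an SV locus")
    z = ((lens - mean) / sd).T  # haplotypes x SVs
    return ExpansionMatrix(smaller, z)


# --------------------------------------------------------------------------
# gene-level VNTR counts and expression correlation
# --------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties and the
    t-approximation p-value; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


@dataclass
class GeneVntrResult:
    table: pd.DataFrame
    r_length: float
    p_length: float
    r_vntr: float
    p_vntr: float
    n_genes: int
    excluded: list[str] = field(default_factory=list)


def gene_vntr_correlation(
    svs: Sequence[SvLocus],
    gene_models: pd.DataFrame,
    expression: pd.DataFrame,
    brain_regions: Sequence[str],
    partition: GenomePartition | None = None,
    offset: float = LOG_OFFSET,
) -> GeneVntrResult:
    """Per-gene VNTR counts (any VNTR overlapping the gene body) and
    Spearman correlations of log10 mean brain TPM with gene length and with
    VNTR count.  Genes absent from the expression table are excluded and
    listed."""
    genes = gene_models[gene_models["type"] == "gene"]
    vntrs = [sv for sv in svs if sv.svclass is SvClass.VNTR]
    trees: dict[str, IntervalTree] = {}
    for i, sv in enumerate(vntrs):
        trees.setdefault(sv.chrom, IntervalTree()).addi(
            sv.start, max(sv.end, sv.start + 1), i
        )
    expr = expression.set_index("gene_id")
    missing_regions = [r for r in brain_regions if r not in expr.columns]
    if missing_regions:
        raise ValueError(f"brain regions absent from expression table: {missing_regions}")
    rows, excluded = [], []
    for row in genes.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", "")
        start0, end = int(row.start) - 1, int(row.end)
        if gene_id not in expr.index:
            excluded.append(gene_id)
            continue
        tree = trees.get(row.seqid)
        n_vntr = len(tree.overlap(start0, end)) if tree is not None else 0
        length = end - start0
        mean_brain = float(expr.loc[gene_id, list(brain_regions)].mean())
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": row.seqid,
                "length_bp": length,
                "vntr_count": n_vntr,
                "vntr_per_kb": n_vntr / (length / 1e3),
                "mean_brain_tpm": mean_brain,
                "log10_tpm": float(np.log10(mean_brain + offset)),
                "subtelomeric": bool(
                    partition.is_subtelomeric(row.seqid, start0)
                )
                if partition
                else False,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        r_len, p_len = spearman(table["length_bp"], table["log10_tpm"])
        r_v, p_v = spearman(table["vntr_count"], table["log10_tpm"])
    else:
        r_len = p_len = r_v = p_v = float("nan")
    table = table.sort_values(
        ["vntr_count", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return GeneVntrResult(
        table=table,
        r_length=r_len,
        p_length=p_len,
        r_vntr=r_v,
        p_vntr=p_v,
        n_genes=len(table),
        excluded=excluded,
    )


# --------------------------------------------------------------------------
# per-chromosome density track (Fig 3-style)
# --------------------------------------------------------------------------


def vntr_density_track(
    svs: Sequence[SvLocus],
    reference: dict[str, str],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Binned VNTR counts and reference GC per chromosome (bedGraph-style)."""
    from svscape.core import gc_fraction

    rows = []
    vntrs = [sv for sv in svs if sv.svclass is SvClass.VNTR]
    for chrom, seq in reference.items():
        for lo in range(0, len(seq), bin_size):
            hi = min(lo + bin_size, len(seq))
            count = sum(1 for sv in vntrs if sv.chrom == chrom and lo <= sv.start < hi)
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "vntr_count": count,
                    "gc": round(gc_fraction(seq[lo:hi]), 4),
                }
            )
    return pd.DataFrame(rows)
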