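"""Synthetic reference and derived haplotypes with planted, truth-tracked
structural variants.

The generator emulates the study design the pipeline is built for: one
reference haplotype plus derived haplotypes that differ by planted VNTR
copy-number changes, mobile-element insertions, deletions, inversions and
background SNVs, together with toy gene models and a per-region expression
table whose brain expression has a configurable rank correlation with gene
length.

Planting model
--------------
A "proto" genome is drawn i.i.d. over {A,C,G,T} (with GC-skewed subtelomeric
blocks).  Each planted locus reserves a window of the proto sequence and
every haplotype receives its own allele there:

* VNTR — the window (subunit length x reference copies) is substituted with
  a tandem array in every haplotype; copy number varies per haplotype.
* MEI — a mobile-element consensus (optionally 5'-truncated by up to 5%) is
  inserted at a point in carrier haplotypes.
* DEL — carriers lose the window.
* INV — carriers have the window reverse-complemented.

Because VNTR substitution is length-preserving on the reference and MEI/DEL
only change carriers, truth coordinates are exact reference coordinates.
Loci are sampled with a minimum separation (default 1 kb) so adjacent
variants never merge into one bubble.  All randomness flows from the config
seed; outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from svscape.config import SimulationConfig
from svscape.core import (
    AssemblySet,
    TruthRecord,
    VariantClass,
    in_intervals,
    karyotype_table,
    revcomp,
    subtelomere_intervals,
)

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)
_EDGE_MARGIN = 2_000  # keep planted loci away from chromosome ends
_TRIM_FLANK = 500


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """An i.i.d. random DNA sequence with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASE_LOOKUP[codes].tobytes().decode()


def _gc_subunit(rng: np.random.Generator, length: int, gc: float) -> str:
    """A repeat subunit with target GC; never a homopolymer."""
    for _ in range(100):
        s = random_sequence(rng, length, gc)
        if len(set(s)) >= 2:
            return s
    raise RuntimeError("could not draw a non-homopolymer subunit")


def generate_reference(
    config: SimulationConfig,
) -> tuple[AssemblySet, pd.DataFrame]:
    """The proto reference genome plus its arm-level karyotype table.

    Subtelomeric blocks (non-acrocentric arm ends) are GC-skewed to
    ``config.subtelomere_gc``; everything else is GC 0.5.
    """
    for c in config.chromosomes:
        if c.length < 2 * config.subtelomere_span:
            raise ValueError(
                f"chromosome {c.name} shorter than twice the subtelomere span"
            )
    rng = np.random.default_rng([config.seed, 1])
    karyotype = karyotype_table(config.chromosomes)
    subtel = subtelomere_intervals(karyotype, config.subtelomere_span)
    seqs: dict[str, str] = {}
    for c in config.chromosomes:
        blocks = sorted(subtel[c.name])
        parts, cursor = [], 0
        for s, e in blocks:
            if s > cursor:
                parts.append(random_sequence(rng, s - cursor, 0.5))
            parts.append(random_sequence(rng, e - s, config.subtelomere_gc))
            cursor = e
        if cursor < c.length:
            parts.append(random_sequence(rng, c.length - cursor, 0.5))
        seqs[c.name] = "".join(parts)
    return AssemblySet(names=["ref"], seqs=[seqs]), karyotype


# --------------------------------------------------------------------------
# variant planting
# --------------------------------------------------------------------------


@dataclass
class PlannedLocus:
    chrom: str
    pos: int  # proto == reference coordinate
    footprint: int  # reference-window length consumed
    vclass: VariantClass
    alleles: list[str]
    subunit: str | None = None
    gc: float | None = None
    family: str | None = None
    subtelomeric: bool = False
    sub_threshold: bool = False


@dataclass
class PlantResult:
    assembly: AssemblySet
    truth: list[TruthRecord]
    #: per truth record, the allele interval in each haplotype's own coordinates
    allele_intervals: list[list[tuple[int, int]]] = field(default_factory=list)


def _interval_choice(
    rng: np.random.Generator, intervals: list[tuple[str, int, int]]
) -> tuple[str, int]:
    """A position uniform over a list of (chrom, start, end) intervals."""
    lengths = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    total = int(lengths.sum())
    if total <= 0:
        raise ValueError("no room left to place a variant")
    r = int(rng.integers(total))
    idx = int(np.searchsorted(np.cumsum(lengths), r, side="right"))
    chrom, s, _ = intervals[idx]
    offset = r - (int(np.cumsum(lengths)[idx]) - int(lengths[idx]))
    return chrom, s + offset


def mei_library(config: SimulationConfig) -> list[tuple[str, str]]:
    """The mobile-element consensus library (one sequence per family),
    derived only from the seed; shared by the planter and the classifier."""
    lib_rng = np.random.default_rng([config.seed, 7])
    return [
        (fam, random_sequence(lib_rng, length)) for fam, length in config.mei_library
    ]


def sample_variant_loci(
    config: SimulationConfig, karyotype: pd.DataFrame, rng: np.random.Generator
) -> list[PlannedLocus]:
    """Draw non-overlapping planted loci with >= ``min_locus_spacing``
    separation; VNTR positions honor ``subtelomeric_vntr_fold``."""
    subtel = subtelomere_intervals(karyotype, config.subtelomere_span)
    lengths = {c.name: c.length for c in config.chromosomes}

    sub_ivs, out_ivs = [], []
    for chrom, length in lengths.items():
        usable = (_EDGE_MARGIN, length - _EDGE_MARGIN)
        blocks = sorted(subtel[chrom])
        cursor = usable[0]
        for s, e in blocks:
            s2, e2 = max(s, usable[0]), min(e, usable[1])
            if e2 > s2:
                sub_ivs.append((chrom, s2, e2))
            if s2 > cursor:
                out_ivs.append((chrom, cursor, s2))
            cursor = max(cursor, e2)
        if usable[1] > cursor:
            out_ivs.append((chrom, cursor, usable[1]))

    a_in = sum(e - s for _, s, e in sub_ivs)
    a_out = sum(e - s for _, s, e in out_ivs)
    f = config.subtelomeric_vntr_fold
    p_sub = (f * a_in) / (f * a_in + a_out) if (f * a_in + a_out) > 0 else 0.0

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    spacing = config.min_locus_spacing

    def _try_place(chrom: str, pos: int, footprint: int) -> bool:
        if pos + footprint + _EDGE_MARGIN > lengths[chrom]:
            return False
        ivs = occupied[chrom]
        lo = (pos - spacing, pos + footprint + spacing)
        i = bisect.bisect_left(ivs, lo)
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if s < lo[1] and lo[0] < e:
                    return False
        ivs.insert(i, (pos, pos + footprint))
        return True

    planned: list[PlannedLocus] = []
    vp = config.vntr
    n_queries = config.n_haplotypes - 1

    def _place(vclass: VariantClass, footprint: int, use_fold: bool) -> tuple[str, int]:
        for _ in range(500):
            if use_fold and a_in > 0 and rng.random() < p_sub:
                chrom, pos = _interval_choice(rng, sub_ivs)
            elif use_fold:
                chrom, pos = _interval_choice(rng, out_ivs)
            else:
                chrom, pos = _interval_choice(rng, sub_ivs + out_ivs)
            if _try_place(chrom, pos, footprint):
                return chrom, pos
        raise RuntimeError("could not place variant after bounded attempts")

    # -- VNTRs (and sub-threshold controls, which are small VNTR deltas)
    for kind in ["VNTR"] * config.n_vntr + ["SUB"] * config.n_subthreshold:
        sub_threshold = kind == "SUB"
        max_len = vp.subunit_len_range[1] if not sub_threshold else 40
        L = int(rng.integers(vp.subunit_len_range[0], max_len + 1))
        gc = float(rng.uniform(*vp.gc_range))
        subunit = _gc_subunit(rng, L, gc)
        c_ref = int(rng.integers(vp.copy_range[0], vp.copy_range[1] + 1))
        copies = [c_ref]
        for _ in range(n_queries):
            d = int(np.rint(rng.normal(0.0, vp.copy_delta_sd)))
            copies.append(max(2, c_ref + d))
        if sub_threshold:
            # keep the allele-length range strictly below the SV threshold
            copies = [c_ref] * config.n_haplotypes
            h = int(rng.integers(1, config.n_haplotypes))
            copies[h] = c_ref + 1  # range == L <= 40 < 50
        else:
            need = -(-vp.min_planted_range // L)  # ceil
            if max(copies) - min(copies) < need:
                h = int(rng.integers(1, config.n_haplotypes))
                # raise h above the minimum of the *other* haplotypes, so the
                # final range is exactly `need` even when h was the minimum
                copies[h] = min(c for i, c in enumerate(copies) if i != h) + need
        footprint = L * copies[0]
        chrom, pos = _place(VariantClass.VNTR, footprint, use_fold=True)
        planned.append(
            PlannedLocus(
                chrom,
                pos,
                footprint,
                VariantClass.VNTR,
                [subunit * c for c in copies],
                subunit=subunit,
                gc=gc,
                sub_threshold=sub_threshold,
            )
        )

    # -- mobile-element library (one consensus per family, seed-fixed)
    library = dict(mei_library(config))
    weights = np.array(config.mei_family_weights, dtype=float)
    weights = weights / weights.sum()
    families = [fam for fam, _ in config.mei_library]

    for _ in range(config.n_mei):
        fam = families[int(rng.choice(len(families), p=weights))]
        consensus = library[fam]
        trunc = int(rng.integers(0, int(0.05 * len(consensus)) + 1))
        ins = consensus[trunc:]
        carriers = _carrier_subset(rng, n_queries)
        alleles = [""] + [ins if c else "" for c in carriers]
        chrom, pos = _place(VariantClass.MEI, 0, use_fold=False)
        planned.append(
            PlannedLocus(chrom, pos, 0, VariantClass.MEI, alleles, family=fam)
        )

    for _ in range(config.n_del):
        size = int(rng.integers(*config.deletion_size_range))
        chrom, pos = _place(VariantClass.DEL, size, use_fold=False)
        carriers = _carrier_subset(rng, n_queries)
        planned.append(
            PlannedLocus(chrom, pos, size, VariantClass.DEL, [None] * 0, family=None)
        )
        planned[-1].alleles = ["__REF__"] + ["" if c else "__REF__" for c in carriers]

    for _ in range(config.n_inv):
        size = int(rng.integers(*config.inversion_size_range))
        chrom, pos = _place(VariantClass.INV, size, use_fold=False)
        carriers = _carrier_subset(rng, n_queries)
        planned.append(
            PlannedLocus(
                chrom,
                pos,
                size,
                VariantClass.INV,
                ["__REF__"] + ["__INV__" if c else "__REF__" for c in carriers],
            )
        )

    subtel_mask = subtel
    for p in planned:
        p.subtelomeric = in_intervals(p.pos, subtel_mask[p.chrom])
    planned.sort(key=lambda p: (p.chrom, p.pos))
    return planned


def _carrier_subset(rng: np.random.Generator, n_queries: int) -> list[bool]:
    """A uniformly random non-empty subset of the query haplotypes."""
    while True:
        carriers = rng.random(n_queries) < 0.5
        if carriers.any():
            return [bool(c) for c in carriers]


def _common_prefix(strings: list[str]) -> int:
    if not strings:
        return 0
    n = min(len(s) for s in strings)
    first = strings[0]
    for i in range(n):
        ch = first[i]
        if any(s[i] != ch for s in strings[1:]):
            return i
    return n


def _trim_locus(
    alleles: list[str], lflank: str, rflank: str
) -> tuple[int, int, tuple[int, ...]]:
    """Longest common prefix/suffix trim of planted alleles in their
    sequence context; returns (prefix, suffix, trimmed lengths)."""
    min_len = min(len(a) for a in alleles)
    p = min(_common_prefix([a + rflank for a in alleles]), min_len)
    s = min(
        _common_prefix([(lflank + a)[::-1] for a in alleles]),
        min_len - p,
    )
    return p, s, tuple(len(a) - p - s for a in alleles)


def plant_variants(
    reference: AssemblySet, config: SimulationConfig
) -> PlantResult:
    """Derive ``n_haplotypes`` sequences from the proto reference with the
    planted alleles substituted and background SNVs applied, and return the
    exact truth records."""
    rng = np.random.default_rng([config.seed, 2])
    karyotype = karyotype_table(config.chromosomes)
    planned = sample_variant_loci(config, karyotype, rng)

    proto = {c: reference.seqs[0][c] for c in reference.chromosomes}
    n_hap = config.n_haplotypes

    # materialize __REF__/__INV__ placeholders
    for p in planned:
        window = proto[p.chrom][p.pos : p.pos + p.footprint]
        p.alleles = [
            window
            if a == "__REF__"
            else revcomp(window)
            if a == "__INV__"
            else a
            for a in p.alleles
        ]

    by_chrom: dict[str, list[PlannedLocus]] = {c: [] for c in proto}
    for p in planned:
        by_chrom[p.chrom].append(p)

    snv_rng = np.random.default_rng([config.seed, 3])
    names = ["ref"] + [f"hap{h}" for h in range(1, n_hap)]
    seqs: list[dict[str, str]] = [dict() for _ in range(n_hap)]
    truth: list[TruthRecord] = []
    allele_intervals: list[list[tuple[int, int]]] = []
    truth_order: list[PlannedLocus] = []

    for chrom, proto_seq in proto.items():
        loci = by_chrom[chrom]
        proto_arr = np.frombuffer(proto_seq.encode(), dtype=np.uint8)
        # SNV-free windows at planted loci
        blocked = np.zeros(len(proto_seq), dtype=bool)
        for p in loci:
            blocked[p.pos : p.pos + max(p.footprint, 1)] = True

        per_hap_offsets = [[] for _ in range(n_hap)]
        hap_chrom_seqs: list[str] = []
        for h in range(n_hap):
            arr = proto_arr.copy()
            hits = np.nonzero(
                (snv_rng.random(len(proto_seq)) < config.snv_rate) & ~blocked
            )[0]
            if hits.size:
                shift = snv_rng.integers(1, 4, size=hits.size).astype(np.uint8)
                codes = _code_of(arr[hits])
                arr[hits] = _BASE_LOOKUP[(codes + shift) % 4]
            mutated = arr.tobytes().decode()
            parts, cursor, out_pos = [], 0, 0
            for p in loci:
                parts.append(mutated[cursor : p.pos])
                out_pos += p.pos - cursor
                per_hap_offsets[h].append((out_pos, out_pos + len(p.alleles[h])))
                parts.append(p.alleles[h])
                out_pos += len(p.alleles[h])
                cursor = p.pos + p.footprint
            parts.append(mutated[cursor:])
            hap_chrom_seqs.append("".join(parts))
        for h in range(n_hap):
            seqs[h][chrom] = hap_chrom_seqs[h]

        for i, p in enumerate(loci):
            lflank = proto_seq[max(0, p.pos - _TRIM_FLANK) : p.pos]
            rflank = proto_seq[p.pos + p.footprint : p.pos + p.footprint + _TRIM_FLANK]
            pre, suf, trimmed = _trim_locus(p.alleles, lflank, rflank)
            truth.append(
                TruthRecord(
                    chrom=chrom,
                    start=p.pos,
                    end=p.pos + p.footprint,
                    vclass=p.vclass,
                    allele_lengths=tuple(len(a) for a in p.alleles),
                    subunit=p.subunit,
                    gc=p.gc,
                    family=p.family,
                    orientation="-" if p.vclass is VariantClass.INV else None,
                    subtelomeric=p.subtelomeric,
                    sub_threshold=p.sub_threshold,
                    trim_start=p.pos + pre,
                    trim_end=p.pos + len(p.alleles[0]) - suf,
                    trimmed_lengths=trimmed,
                )
            )
            allele_intervals.append([per_hap_offsets[h][i] for h in range(n_hap)])
            truth_order.append(p)

    assembly = AssemblySet(names=names, seqs=seqs)
    return PlantResult(assembly=assembly, truth=truth, allele_intervals=allele_intervals)


def _code_of(ascii_codes: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    return table[ascii_codes]


def simulate(config: SimulationConfig) -> tuple[PlantResult, pd.DataFrame]:
    """Reference generation + planting in one call; returns the plant result
    and the karyotype table."""
    reference, karyotype = generate_reference(config)
    return plant_variants(reference, config), karyotype


# --------------------------------------------------------------------------
# gene models and expression
# --------------------------------------------------------------------------


def generate_gene_models_and_expression(
    config: SimulationConfig, karyotype: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene models plus a per-region expression table.

    Returns ``(features, expression)``: ``features`` holds GFF3-style rows
    (gene/mRNA/exon/CDS/UTR with phases) and ``expression`` one row per gene
    with median-TPM columns per tissue region.  The Spearman correlation of
    gene length with log10 mean brain TPM is controlled by
    ``config.expression.length_correlation`` (1.0 forces exact monotonicity).
    """
    gp, xp = config.gene, config.expression
    rho = xp.length_correlation
    if not -1.0 <= rho <= 1.0:
        raise ValueError("length correlation must be in [-1, 1]")
    rng = np.random.default_rng([config.seed, 4])
    lengths_by_chrom = {
        c: int(g["end"].max()) for c, g in karyotype.groupby("chrom", sort=False)
    }
    chroms = list(lengths_by_chrom)
    sizes = np.array([lengths_by_chrom[c] for c in chroms], dtype=float)

    feature_rows: list[tuple] = []
    genes: list[tuple[str, str, int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    used_lengths: set[int] = set()
    lo, hi = np.log(gp.length_range[0]), np.log(gp.length_range[1])

    for g_idx in range(gp.n_genes):
        gene_id = f"G{g_idx + 1:05d}"
        for _ in range(500):
            length = int(np.exp(rng.uniform(lo, hi)))
            chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
            max_start = lengths_by_chrom[chrom] - length - 1
            if max_start <= 1:
                continue
            start = int(rng.integers(1, max_start))
            iv = (start - 500, start + length + 500)
            i = bisect.bisect_left(occupied[chrom], iv)
            clash = False
            for j in (i - 1, i):
                if 0 <= j < len(occupied[chrom]):
                    s, e = occupied[chrom][j]
                    if s < iv[1] and iv[0] < e:
                        clash = True
            if clash:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            rows = _gene_features(rng, gene_id, chrom, start, length, strand, gp)
            end = int(rows[0][4])  # realized gene end (exon-width rounding)
            # distinct realized lengths keep rank correlations tie-free
            if end - start in used_lengths or end > lengths_by_chrom[chrom]:
                continue
            used_lengths.add(end - start)
            occupied[chrom].insert(i, iv)
            genes.append((gene_id, chrom, start, end, strand))
            feature_rows.extend(rows)
            break
        else:
            raise RuntimeError("could not place gene after bounded attempts")

    features = pd.DataFrame(
        feature_rows,
        columns=[
            "seqid",
            "source",
            "type",
            "start",
            "end",
            "score",
            "strand",
            "phase",
            "attributes",
        ],
    )

    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    expression = _expression_table(rng, gene_df, xp, rho)
    return features, expression


def _gene_features(rng, gene_id, chrom, start, length, strand, gp):
    """gene / mRNA / exon / CDS / UTR rows (1-based inclusive, GFF3)."""
    n_ex = int(rng.integers(gp.exon_count_range[0], gp.exon_count_range[1] + 1))
    n_blocks = 2 * n_ex - 1
    w = rng.random(n_blocks) + 0.25
    widths = np.maximum((w / w.sum() * length).astype(int), 30)
    widths[-1] = max(30, length - int(widths[:-1].sum()))
    bounds = np.concatenate([[0], np.cumsum(widths)])
    exons = [
        (start + int(bounds[i]), start + int(bounds[i + 1]))
        for i in range(n_blocks)
        if i % 2 == 0
    ]
    end = exons[-1][1]
    rows = [
        (chrom, "svscape", "gene", start + 1, end, ".", strand, ".", f"ID={gene_id}"),
        (
            chrom,
            "svscape",
            "mRNA",
            start + 1,
            end,
            ".",
            strand,
            ".",
            f"ID={gene_id}.t1;Parent={gene_id}",
        ),
    ]
    exonic = sum(e - s for s, e in exons)
    u5 = min(150, max(1, exons[0][1] - exons[0][0] - 1))
    u3 = min(150, max(1, exons[-1][1] - exons[-1][0] - 1))
    if exonic - u5 - u3 < 3:
        u5 = u3 = 0
    # genomic order: UTR5 at the transcription start for '+', at the end for '-'
    left_u, right_u = (u5, u3) if strand == "+" else (u3, u5)
    cds_phase, consumed = 0, 0
    for k, (s, e) in enumerate(exons):
        rows.append(
            (chrom, "svscape", "exon", s + 1, e, ".", strand, ".",
             f"ID={gene_id}.e{k + 1};Parent={gene_id}.t1")
        )
    cursor = 0
    for k, (s, e) in enumerate(exons):
        ex_len = e - s
        seg_start, seg_end = s, e
        # carve UTRs off the outer exons
        if cursor < left_u:
            take = min(left_u - cursor, ex_len)
            utype = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
            rows.append(
                (chrom, "svscape", utype, s + 1, s + take, ".", strand, ".",
                 f"Parent={gene_id}.t1")
            )
            seg_start = s + take
        right_from = exonic - right_u
        if cursor + ex_len > right_from:
            cut = max(right_from - cursor, 0)
            utype = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
            rows.append(
                (chrom, "svscape", utype, s + cut + 1, e, ".", strand, ".",
                 f"Parent={gene_id}.t1")
            )
            seg_end = s + cut
        if seg_end > seg_start:
            rows.append(
                (chrom, "svscape", "CDS", seg_start + 1, seg_end, ".", strand,
                 str(cds_phase), f"Parent={gene_id}.t1")
            )
            consumed += seg_end - seg_start
            cds_phase = (3 - consumed % 3) % 3
        cursor += ex_len
    return rows


def _expression_table(rng, gene_df, xp, rho):
    n = len(gene_df)
    cols = ["gene_id"] + list(xp.regions)
    if n == 0:
        return pd.DataFrame(columns=cols)
    lengths = (gene_df["end"] - gene_df["start"]).to_numpy(float)
    # Gaussian copula on normal scores; sin transform maps the target
    # Spearman rho to the Pearson rho of the latent normals
    order = np.argsort(np.argsort(lengths, kind="stable"), kind="stable")
    z_len = _normal_scores(order, n)
    if abs(rho) >= 1.0:
        z_expr = np.sign(rho) * z_len
    else:
        rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
        noise = rng.standard_normal(n)
        z_expr = rho_p * z_len + np.sqrt(1.0 - rho_p**2) * noise
    mean_brain = 10.0 ** (0.8 * z_expr + 0.5)  # lognormal-ish TPM scale

    table = {"gene_id": gene_df["gene_id"].to_numpy()}
    brain = list(xp.brain_regions)
    jitter = {}
    for r in xp.regions:
        if r in brain:
            jitter[r] = np.exp(rng.normal(0.0, 0.1, size=n))
        else:
            table[r] = np.round(10.0 ** rng.normal(0.3, 0.8, size=n), 4)
    if brain:
        j = np.vstack([jitter[r] for r in brain])
        j = j / j.mean(axis=0, keepdims=True)  # row means stay exact
        for i, r in enumerate(brain):
            table[r] = np.round(mean_brain * j[i], 6)
    return pd.DataFrame(table, columns=cols)


def _normal_scores(rank0: np.ndarray, n: int) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf((rank0 + 1.0) / (n + 1.0))
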