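"""Shared domain types for the SV compendium pipeline.

Coordinates are 0-based, half-open on the designated reference haplotype
unless a field name says otherwise.  Haplotype 0 is the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class VariantClass(str, Enum):
    VNTR = "VNTR"
    MEI = "MEI"
    INV = "INV"
    DEL = "DEL"
    OTHER = "OTHER"


class SvClass(str, Enum):
    VNTR = "VNTR"
    MEI = "MEI"
    INV_ASSOCIATED = "INV-associated"
    OTHER = "OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"


class Region(str, Enum):
    CDS = "CDS"
    UTR = "UTR"
    INTRON = "intron"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class TruthRecord:
    """A planted variant: reference interval, class, and exact per-haplotype
    allele lengths, plus the planted attributes needed to check recovery."""

    chrom: str
    start: int
    end: int
    vclass: VariantClass
    allele_lengths: tuple[int, ...]
    subunit: str | None = None
    gc: float | None = None
    family: str | None = None
    orientation: str | None = None
    subtelomeric: bool = False
    sub_threshold: bool = False
    # parsimony-normalized representation: the planted alleles with their
    # longest common prefix/suffix (in sequence context) trimmed away; this
    # is the minimal locus a boundary-exact caller should report.
    trim_start: int = -1
    trim_end: int = -1
    trimmed_lengths: tuple[int, ...] | None = None

    @property
    def length_range(self) -> int:
        return max(self.allele_lengths) - min(self.allele_lengths)


@dataclass(frozen=True)
class Anchor:
    """An exact match shared by all haplotypes, occurring exactly once in
    each haplotype's current interval.  ``starts[h]`` is the 0-based offset
    of the match in haplotype ``h``."""

    length: int
    starts: tuple[int, ...]
    exact: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("anchor length must be positive")


@dataclass
class Bubble:
    """The divergent region between two consecutive anchors."""

    chrom: str
    ref_start: int
    ref_end: int
    alleles: list[str]
    spanned: tuple[bool, ...]
    aligned: bool = True  # False when the longest allele exceeds the cap
    left_anchor: int = -1
    right_anchor: int = -1

    @property
    def max_allele(self) -> int:
        return max(len(a) for a in self.alleles)


@dataclass
class VariantLocus:
    """A run of low-confidence alignment columns: one allele per haplotype."""

    chrom: str
    start: int
    end: int
    alleles: list[str]
    spanned: tuple[bool, ...]

    @property
    def allele_lengths(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.alleles)


@dataclass(frozen=True)
class TandemRepeat:
    """Best-scoring tandem repeat of an allele (wraparound-DP score)."""

    period: int
    consensus: str
    copies: float
    score: int
    gc: float
    entropy: float
    span_fraction: float
    tract_start: int = 0
    tract_end: int = 0

    @property
    def consensus_bin(self) -> str:
        if self.period < 6:
            return "<6"
        if self.period <= 100:
            return "6-100"
        if self.period <= 1000:
            return "100-1000"
        return ">1000"


@dataclass
class SvLocus:
    """A variant locus with SV status and downstream annotations."""

    chrom: str
    start: int
    end: int
    alleles: list[str]
    spanned: tuple[bool, ...]
    is_sv: bool = False
    fully_assessed: bool = True
    unique_to: int | None = None
    svclass: SvClass = SvClass.UNCLASSIFIED
    mei_family: str | None = None
    repeat: TandemRepeat | None = None
    region: Region | None = None
    subtelomeric: bool = False
    inversion_ambiguous: bool = False

    @property
    def allele_lengths(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.alleles)

    @property
    def length_range(self) -> int:
        lens = [len(a) for a, s in zip(self.alleles, self.spanned) if s]
        return max(lens) - min(lens) if lens else 0


@dataclass(frozen=True)
class Segment:
    """An oriented query-to-reference mapping from the pairwise comparison."""

    query_id: str
    q_start: int
    q_end: int
    chrom: str
    r_start: int
    r_end: int
    orientation: str  # '+' or '-'
    order_ref: int = -1
    order_query: int = -1

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.r_end <= self.r_start:
            raise ValueError("segment intervals must be non-empty")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def ref_length(self) -> int:
        return self.r_end - self.r_start


@dataclass(frozen=True)
class InversionCall:
    """An inverted segment enclosed by larger, consistently oriented
    segments that are consecutive on both reference and query."""

    chrom: str
    start: int
    end: int
    query_id: str
    flank_ids: tuple[int, int] = (-1, -1)
    zygosity: str = "n/a"  # het | hom | n/a
    ambiguous: bool = False


@dataclass
class AssemblySet:
    """Named haplotype sequence collections.

    Haplotype 0 is the designated reference.  A haplotype missing a
    chromosome is treated as unspanned for that whole chromosome.
    """

    names: list[str]
    seqs: list[dict[str, str]]  # per haplotype: chromosome -> sequence

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and sequence collections differ in length")

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.seqs[0].keys())

    def get(self, haplotype: int, chrom: str) -> str | None:
        return self.seqs[haplotype].get(chrom)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def karyotype_table(chromosomes) -> pd.DataFrame:
    """Arm-level karyotype: one row per chromosome arm with 0-based
    half-open bounds and the acrocentric flag (p arms only)."""
    rows = []
    for c in chromosomes:
        rows.append((c.name, "p", 0, c.centromere, c.acrocentric_p))
        rows.append((c.name, "q", c.centromere, c.length, False))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end", "acrocentric"])


def chromosome_lengths(karyotype: pd.DataFrame) -> dict[str, int]:
    return {c: int(g["end"].max()) for c, g in karyotype.groupby("chrom", sort=False)}


def subtelomere_intervals(
    karyotype: pd.DataFrame, span: int
) -> dict[str, list[tuple[int, int]]]:
    """Terminal ``span`` bp of every chromosome arm, excluding acrocentric
    arms.  ``span`` may not exceed any chromosome length."""
    lengths = chromosome_lengths(karyotype)
    for chrom, length in lengths.items():
        if span > length:
            raise ValueError(f"subtelomere span {span} exceeds {chrom} length {length}")
    mask: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    if span == 0:
        return mask
    for _, row in karyotype.iterrows():
        if row["acrocentric"]:
            continue
        length = lengths[row["chrom"]]
        if row["arm"] == "p":
            iv = (0, min(span, row["end"]))
        else:
            iv = (max(length - span, row["start"]), length)
        if iv[1] > iv[0]:
            mask[row["chrom"]].append(iv)
    return mask


def in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = sum(1 for b in seq if b in "GCgc")
    return gc / len(seq)


def shannon_entropy(seq: str) -> float:
    """Base-composition entropy in bits (0 for a homopolymer, 2 for uniform)."""
    if not seq:
        return 0.0
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())
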