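"""Readers and writers for the standard formats the pipeline touches.

Conventions: BED is 0-based half-open; GFF3 and VCF are 1-based (inclusive
for GFF3); GFA is version 1.0.  Coordinate conversion happens exactly once,
here at the boundary.  FASTA goes through Biopython, VCF through pysam.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from svscape.core import SvLocus

GFF3_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


# -- BED --------------------------------------------------------------------


def read_bed(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: BED end < start")
            if chrom_lengths is not None and fields[0] not in chrom_lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {fields[0]!r}")
            rows.append((fields[0], start, end, *fields[3:]))
    n_extra = max((len(r) - 3 for r in rows), default=0)
    cols = ["chrom", "start", "end"] + [
        n for n, _ in zip(["name", "score", "strand"], range(n_extra))
    ]
    cols += [f"col{i}" for i in range(len(cols), 3 + n_extra)]
    rows = [tuple(r) + ("",) * (3 + n_extra - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=cols)


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# -- GFF3 -------------------------------------------------------------------


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse a GFF3 file into a frame with 1-based inclusive coordinates.

    Malformed lines raise with the file name and line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 fields, "
                    f"got {len(fields)}"
                )
            try:
                fields[3], fields[4] = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if fields[4] < fields[3]:
                raise ValueError(f"{path}:{lineno}: end < start")
            rows.append(tuple(fields))
    return pd.DataFrame(rows, columns=GFF3_COLUMNS)


def write_gff3(path: str | Path, features: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# -- GFA 1.0 ----------------------------------------------------------------


def write_gfa(
    path_or_none: str | Path | None,
    segments: Sequence[tuple[str, str | None, int]],
    links: Sequence[tuple[str, str, str, str, dict]],
) -> str:
    """Serialize S-lines (name, sequence-or-None, length) and L-lines
    (from, from_orient, to, to_orient, tags); returns the text."""
    lines = ["H\tVN:Z:1.0"]
    for name, seq, length in segments:
        lines.append(f"S\t{name}\t{seq or '*'}\tLN:i:{length}")
    for a, ao, b, bo, tags in links:
        tag_text = "".join(
            f"\t{k}:{'i' if isinstance(v, int) else 'Z'}:{v}" for k, v in tags.items()
        )
        lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M{tag_text}")
    text = "\n".join(lines) + "\n"
    if path_or_none is not None:
        Path(path_or_none).write_text(text)
    return text


def parse_gfa(text: str) -> tuple[list[tuple[str, str | None, int]], list[tuple]]:
    segments, links = [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line:
            continue
        fields = line.split("\t")
        if fields[0] == "S":
            seq = None if fields[2] == "*" else fields[2]
            length = None
            for tag in fields[3:]:
                if tag.startswith("LN:i:"):
                    length = int(tag[5:])
            if length is None:
                length = len(seq) if seq else 0
            segments.append((fields[1], seq, length))
        elif fields[0] == "L":
            tags = {}
            for tag in fields[6:]:
                name, typ, val = tag.split(":", 2)
                tags[name] = int(val) if typ == "i" else val
            links.append((fields[1], fields[2], fields[3], fields[4], tags))
        elif fields[0] not in "H#C P":
            raise ValueError(f"GFA line {lineno}: unknown record type {fields[0]!r}")
    return segments, links


# -- VCF --------------------------------------------------------------------


def write_vcf(
    path: str | Path,
    svs: Sequence[SvLocus],
    sample_names: Sequence[str],
    reference: dict[str, str],
    chrom_lengths: dict[str, int],
) -> None:
    """Multi-allelic, sequence-resolved VCF 4.2: one record per locus, the
    reference allele as REF, distinct alternates as ALTs, haploid GT per
    haplotype sample.  Loci with an empty allele are left-anchored with one
    preceding reference base."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=SVCLASS,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Locus end">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid call">')
    for s in sample_names:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
            alleles = list(sv.alleles)
            anchored = any(len(a) == 0 for a in alleles)
            pos0 = sv.start - 1 if anchored else sv.start
            if anchored:
                base = reference[sv.chrom][sv.start - 1]
                alleles = [base + a for a in alleles]
            ref_allele = alleles[0]
            alts: list[str] = []
            for a in alleles[1:]:
                if a != ref_allele and a not in alts:
                    alts.append(a)
            if not alts:
                continue  # monomorphic across haplotypes: nothing to emit
            rec = vcf.new_record(
                contig=sv.chrom,
                start=pos0,
                alleles=[ref_allele] + alts,
            )
            rec.stop = pos0 + len(ref_allele)
            rec.info["SVCLASS"] = str(sv.svclass.value)
            allele_index = {ref_allele: 0}
            for i, a in enumerate(alts, start=1):
                allele_index[a] = i
            for s_name, a in zip(sample_names, alleles):
                rec.samples[s_name]["GT"] = (allele_index.get(a, 0),)
            vcf.write(rec)


def read_vcf(path: str | Path):
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        records = []
        for rec in vcf:
            calls = [rec.samples[s]["GT"][0] for s in samples]
            records.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,  # 1-based
                    "alleles": list(rec.alleles),
                    "calls": calls,
                    "svclass": rec.info.get("SVCLASS"),
                }
            )
    return samples, records


# -- misc -------------------------------------------------------------------


def bed_to_vcf_pos(start0: int, anchored: bool) -> int:
    """BED start -> VCF POS (1-based; anchored records move one base left)."""
    return start0 if anchored else start0 + 1


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
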