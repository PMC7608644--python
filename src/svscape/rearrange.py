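"""Pairwise query-vs-reference breakpoint analysis.

Unique exact matches (both strands) are chained by a dynamic program that
maximizes total matched length minus a per-breakpoint penalty; runs of
colinear matches become oriented segments that tile the mapped portion of
the query.  Segments feed a breakpoint graph (GFA 1.0, query-adjacency
edges flagged when the reference adjacency is non-colinear) and the
inversion caller: a segment is an inversion when it is enclosed by larger
segments of the opposite orientation from the same query contig,
consecutive on both the reference and the query axis.

The chaining DP uses a bounded lookback window over the query-sorted
matches; with matches unique on both axes this is exact in practice and
keeps the scan linear.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from svscape.anchors import encode, kmer_hashes, _unique_once
from svscape.config import PipelineConfig
from svscape.core import InversionCall, Segment, revcomp
from svscape.io import write_gfa

_LOOKBACK = 64


def _unique_matches(
    query: str, reference: str, k: int
) -> list[tuple[int, int, int, str]]:
    """Maximal runs of k-mers unique in the reference and unique across both
    strands of the query; returns (length, ref_start, query_start, orient)
    with query coordinates always on the forward strand."""
    ref_h = kmer_hashes(encode(reference), k)
    q_fwd = kmer_hashes(encode(query), k)
    q_rev = kmer_hashes(encode(revcomp(query)), k)
    if ref_h.size == 0 or q_fwd.size == 0:
        return []
    v_ref, p_ref = _unique_once(ref_h)
    ok = v_ref >= 0
    v_ref, p_ref = v_ref[ok], p_ref[ok]
    combined = np.concatenate([q_fwd, q_rev])
    v_q, p_q = _unique_once(combined)
    ok = v_q >= 0
    v_q, p_q = v_q[ok], p_q[ok]
    shared = v_ref[np.isin(v_ref, v_q, assume_unique=True)]
    if shared.size == 0:
        return []
    r_pos = p_ref[np.searchsorted(v_ref, shared)]
    q_pos = p_q[np.searchsorted(v_q, shared)]
    n_fwd = q_fwd.size
    strand = q_pos < n_fwd  # True: forward
    order = np.argsort(r_pos, kind="stable")
    r_pos, q_pos, strand = r_pos[order], q_pos[order], strand[order]

    matches = []
    i = 0
    n = r_pos.size
    Lq = len(query)
    while i < n:
        j = i
        while (
            j + 1 < n
            and r_pos[j + 1] == r_pos[j] + 1
            and strand[j + 1] == strand[j]
            and q_pos[j + 1] == q_pos[j] + 1
        ):
            j += 1
        length = int(r_pos[j] - r_pos[i]) + k
        if strand[i]:
            matches.append((length, int(r_pos[i]), int(q_pos[i]), "+"))
        else:
            # q_pos is on the reverse strand; map the run back to forward
            rev_start = int(q_pos[i]) - n_fwd
            fwd_start = Lq - (rev_start + length)
            matches.append((length, int(r_pos[i]), fwd_start, "-"))
        i = j + 1
    return matches


def _colinear(a: tuple, b: tuple) -> bool:
    """b extends a's segment: same orientation and consistent reference
    order along the query."""
    la, ra, qa, oa = a
    lb, rb, qb, ob = b
    if oa != ob:
        return False
    if oa == "+":
        return rb >= ra + la and qb >= qa + la
    return rb + lb <= ra and qb >= qa + la


def chain_segments(
    query: str,
    reference: str,
    config: PipelineConfig,
    query_id: str = "query",
    chrom: str = "ref",
) -> list[Segment]:
    """Oriented segments of the query against the reference.  Empty when no
    unique matches exist (the contig is unplaced)."""
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    matches = _unique_matches(query, reference, config.min_anchor_length)
    if not matches:
        return []
    matches.sort(key=lambda m: m[2])
    penalty = config.effective_breakpoint_penalty
    n = len(matches)
    score = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=np.int64)
    for i, m in enumerate(matches):
        score[i] = m[0] - penalty  # opening its own segment costs one breakpoint
        for j in range(max(0, i - _LOOKBACK), i):
            if score[j] == -np.inf:
                continue
            step = score[j] + m[0] - (0 if _colinear(matches[j], m) else penalty)
            if step > score[i]:
                score[i] = step
                prev[i] = j
    end = int(np.argmax(score))
    chain = []
    while end >= 0:
        chain.append(matches[end])
        end = int(prev[end])
    chain.reverse()

    # group consecutive colinear matches into segments
    groups: list[list[tuple]] = [[chain[0]]]
    for m in chain[1:]:
        if _colinear(groups[-1][-1], m):
            groups[-1].append(m)
        else:
            groups.append([m])
    segments = []
    for g in groups:
        q_start = g[0][2]
        q_end = g[-1][2] + g[-1][0]
        r_coords = [m[1] for m in g] + [m[1] + m[0] for m in g]
        segments.append(
            Segment(
                query_id=query_id,
                q_start=q_start,
                q_end=q_end,
                chrom=chrom,
                r_start=min(r_coords),
                r_end=max(r_coords),
                orientation=g[0][3],
            )
        )
    return assign_orders(segments)


def assign_orders(segments: Sequence[Segment]) -> list[Segment]:
    """Order indices: query rank within each contig, reference rank within
    each chromosome (over that contig's segments)."""
    from dataclasses import replace

    out = list(segments)
    by_contig: dict[str, list[int]] = {}
    for i, s in enumerate(out):
        by_contig.setdefault(s.query_id, []).append(i)
    for idxs in by_contig.values():
        q_rank = sorted(idxs, key=lambda i: out[i].q_start)
        for rank, i in enumerate(q_rank):
            out[i] = replace(out[i], order_query=rank)
        by_chrom: dict[str, list[int]] = {}
        for i in idxs:
            by_chrom.setdefault(out[i].chrom, []).append(i)
        for c_idxs in by_chrom.values():
            r_rank = sorted(c_idxs, key=lambda i: out[i].r_start)
            for rank, i in enumerate(r_rank):
                out[i] = replace(out[i], order_ref=rank)
    return out


def segments_bed(segments: Sequence[Segment]) -> pd.DataFrame:
    """Ordered/oriented segment table (BED-style: score = query order
    index, strand = orientation)."""
    rows = [
        (s.chrom, s.r_start, s.r_end, s.query_id, s.order_query, s.orientation)
        for s in sorted(segments, key=lambda s: (s.chrom, s.r_start))
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def build_breakpoint_graph(
    segments_per_contig: dict[str, list[Segment]],
) -> tuple[nx.MultiDiGraph, str]:
    """Breakpoint graph: nodes are segments, edges connect query-adjacent
    segments; an edge carries BP:i:1 when the reference adjacency is
    non-colinear (a rearrangement breakpoint), BP:i:0 otherwise."""
    graph = nx.MultiDiGraph()
    gfa_segments = []
    gfa_links = []
    for contig, segments in sorted(segments_per_contig.items()):
        ordered = sorted(segments, key=lambda s: s.order_query)
        names = []
        for s in ordered:
            name = f"{contig}.{s.order_query}"
            names.append(name)
            graph.add_node(name, segment=s)
            gfa_segments.append((name, None, s.r_end - s.r_start))
        for a, b in zip(ordered, ordered[1:]):
            colinear = (
                a.orientation == b.orientation
                and a.chrom == b.chrom
                and (
                    (a.orientation == "+" and b.r_start >= a.r_end)
                    or (a.orientation == "-" and b.r_end <= a.r_start)
                )
            )
            bp = 0 if colinear else 1
            na, nb = f"{contig}.{a.order_query}", f"{contig}.{b.order_query}"
            graph.add_edge(na, nb, breakpoint=bool(bp))
            gfa_links.append((na, a.orientation, nb, b.orientation, {"BP": bp}))
    return graph, write_gfa(None, gfa_segments, gfa_links)


def call_inversions(
    segments: Sequence[Segment],
    vntr_loci: Sequence[tuple[str, int, int]] | None = None,
) -> list[InversionCall]:
    """Enclosure rule: for every query-consecutive triple (A, B, C) from one
    contig, call B's reference interval an inversion iff B's orientation is
    opposite to both flanks, both flanks are strictly larger than B, all
    three map to one chromosome, and the three are consecutive on the
    reference axis too.  Calls whose interval lies inside a VNTR locus are
    flagged ambiguous, not dropped."""
    calls = []
    by_contig: dict[str, list[Segment]] = {}
    for s in segments:
        by_contig.setdefault(s.query_id, []).append(s)
    for contig, segs in sorted(by_contig.items()):
        ordered = sorted(segs, key=lambda s: s.order_query)
        for a, b, c in zip(ordered, ordered[1:], ordered[2:]):
            if not (a.orientation == c.orientation != b.orientation):
                continue
            if not (a.chrom == b.chrom == c.chrom):
                continue
            if b.ref_length >= a.ref_length or b.ref_length >= c.ref_length:
                continue
            ranks = sorted((a.order_ref, b.order_ref, c.order_ref))
            if ranks != list(range(ranks[0], ranks[0] + 3)):
                continue
            ambiguous = False
            if vntr_loci:
                for chrom, lo, hi in vntr_loci:
                    if chrom == b.chrom and lo <= b.r_start and b.r_end <= hi:
                        ambiguous = True
                        break
            calls.append(
                InversionCall(
                    chrom=b.chrom,
                    start=b.r_start,
                    end=b.r_end,
                    query_id=contig,
                    flank_ids=(a.order_query, c.order_query),
                    ambiguous=ambiguous,
                )
            )
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.query_id))


def zygosity_across_haplotypes(
    calls_h1: Sequence[InversionCall],
    calls_h2: Sequence[InversionCall],
    min_reciprocal: float = 0.5,
) -> list[InversionCall]:
    """Merge one diploid pair's calls: calls reciprocally overlapping
    >= min_reciprocal across the two haplotypes become one homozygous call;
    the rest are heterozygous."""
    from dataclasses import replace

    used = set()
    out = []
    for c1 in calls_h1:
        mate = None
        for k, c2 in enumerate(calls_h2):
            if k in used or c2.chrom != c1.chrom:
                continue
            ov = min(c1.end, c2.end) - max(c1.start, c2.start)
            if ov <= 0:
                continue
            if ov / (c1.end - c1.start) >= min_reciprocal and ov / (
                c2.end - c2.start
            ) >= min_reciprocal:
                mate = k
                break
        if mate is None:
            out.append(replace(c1, zygosity="het"))
        else:
            used.add(mate)
            out.append(replace(c1, zygosity="hom"))
    for k, c2 in enumerate(calls_h2):
        if k not in used:
            out.append(replace(c2, zygosity="het"))
    return sorted(out, key=lambda c: (c.chrom, c.start, c.query_id))
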