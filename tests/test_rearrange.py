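"""Segment chaining, breakpoint graph, inversion calling, zygosity."""

from __future__ import annotations

import numpy as np
import pytest

from svscape.config import PipelineConfig
from svscape.core import InversionCall, Segment, revcomp
from svscape.io import parse_gfa
from svscape.rearrange import (
    assign_orders,
    build_breakpoint_graph,
    call_inversions,
    chain_segments,
    segments_bed,
    zygosity_across_haplotypes,
)

CFG = PipelineConfig()


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def test_identity_single_forward_segment():
    rng = np.random.default_rng(0)
    ref = _rand(rng, 20_000)
    segs = chain_segments(ref, ref, CFG, query_id="q", chrom="c")
    assert len(segs) == 1
    s = segs[0]
    assert s.orientation == "+" and s.q_start == 0 and s.q_end == len(ref)
    assert (s.r_start, s.r_end) == (0, len(ref))
    assert (s.order_ref, s.order_query) == (0, 0)


def test_middle_inversion_three_segments_and_call():
    rng = np.random.default_rng(1)
    ref = _rand(rng, 30_000)
    query = ref[:12_000] + revcomp(ref[12_000:15_000]) + ref[15_000:]
    segs = chain_segments(query, ref, CFG, query_id="q", chrom="c")
    assert [s.orientation for s in sorted(segs, key=lambda s: s.order_query)] == [
        "+", "-", "+",
    ]
    calls = call_inversions(segs)
    assert len(calls) == 1
    c = calls[0]
    assert abs(c.start - 12_000) <= CFG.min_anchor_length
    assert abs(c.end - 15_000) <= CFG.min_anchor_length
    assert not c.ambiguous
    # inside a VNTR interval the call survives but is flagged
    flagged = call_inversions(segs, vntr_loci=[("c", 11_000, 16_000)])
    assert len(flagged) == 1 and flagged[0].ambiguous
    # a VNTR interval elsewhere leaves the call clean
    assert not call_inversions(segs, vntr_loci=[("c", 0, 5_000)])[0].ambiguous


def test_breakpoint_graph_flags_inversion_edges():
    rng = np.random.default_rng(2)
    ref = _rand(rng, 30_000)
    query = ref[:12_000] + revcomp(ref[12_000:15_000]) + ref[15_000:]
    segs = chain_segments(query, ref, CFG, query_id="q", chrom="c")
    graph, gfa = build_breakpoint_graph({"q": segs})
    assert graph.number_of_nodes() == 3 and graph.number_of_edges() == 2
    assert all(d["breakpoint"] for _, _, d in graph.edges(data=True))
    names, links = parse_gfa(gfa)
    assert len(names) == 3 and len(links) == 2
    assert all(tags.get("BP") == 1 for *_, tags in links)
    # identity comparison: one node, no edges
    segs_id = chain_segments(ref, ref, CFG, query_id="q", chrom="c")
    g2, gfa2 = build_breakpoint_graph({"q": segs_id})
    assert g2.number_of_nodes() == 1 and g2.number_of_edges() == 0


def test_penalty_sweep_segment_count_non_increasing():
    import dataclasses

    rng = np.random.default_rng(3)
    ref = _rand(rng, 20_000)
    # query with scattered SNVs creating many short exact matches
    arr = list(ref)
    for pos in rng.choice(len(arr), size=60, replace=False):
        arr[int(pos)] = "ACGT"[int(rng.integers(4))]
    query = "".join(arr)
    counts = []
    for penalty in (10, 100, 1_000, 10_000):
        cfg = dataclasses.replace(CFG, breakpoint_penalty=penalty)
        counts.append(len(chain_segments(query, ref, cfg)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_empty_inputs_rejected_and_unplaced_contig():
    with pytest.raises(ValueError):
        chain_segments("", "ACGT" * 100, CFG)
    with pytest.raises(ValueError):
        chain_segments("ACGT" * 100, "", CFG)
    rng = np.random.default_rng(4)
    # no shared unique matches: unplaced, no segments
    assert chain_segments(_rand(rng, 500), _rand(rng, 500), CFG) == []


def _seg(q_start, r_start, length, orientation, contig="q", chrom="c"):
    return Segment(
        query_id=contig,
        q_start=q_start,
        q_end=q_start + length,
        chrom=chrom,
        r_start=r_start,
        r_end=r_start + length,
        orientation=orientation,
    )


def test_inversion_rule_requires_strictly_smaller_middle():
    def triple(mid_len):
        return assign_orders(
            [
                _seg(0, 0, 500, "+"),
                _seg(500, 500, mid_len, "-"),
                _seg(500 + mid_len, 500 + mid_len, 500, "+"),
            ]
        )

    assert len(call_inversions(triple(499))) == 1
    assert call_inversions(triple(500)) == []  # equality fails the rule


def test_inversion_rule_requires_reference_consecutiveness():
    # B maps far away on the reference: an extra segment sits between on the
    # reference axis, breaking consecutiveness
    segs = assign_orders(
        [
            _seg(0, 0, 500, "+"),
            _seg(500, 5_000, 100, "-"),
            _seg(600, 600, 500, "+"),
            _seg(1_100, 2_000, 400, "+"),
        ]
    )
    assert call_inversions(segs) == []


def test_zygosity_merge():
    a = InversionCall("c", 1_000, 2_000, "h1")
    b = InversionCall("c", 1_100, 2_100, "h2")  # 90% reciprocal
    merged = zygosity_across_haplotypes([a], [b])
    assert len(merged) == 1 and merged[0].zygosity == "hom"
    # 40% reciprocal overlap: two het calls
    c = InversionCall("c", 1_600, 3_200, "h2")
    merged = zygosity_across_haplotypes([a], [c])
    assert sorted(m.zygosity for m in merged) == ["het", "het"]
    merged = zygosity_across_haplotypes([a], [])
    assert len(merged) == 1 and merged[0].zygosity == "het"


def test_segment_table_and_order_invariance():
    segs = assign_orders(
        [
            _seg(0, 0, 500, "+"),
            _seg(500, 700, 100, "-"),
            _seg(600, 900, 300, "+"),
        ]
    )
    table = segments_bed(segs)
    assert list(table["start"]) == sorted(table["start"])
    calls_fwd = call_inversions(segs)
    calls_rev = call_inversions(list(reversed(segs)))
    assert calls_fwd == calls_rev
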