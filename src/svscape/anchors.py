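"""Colinear anchoring of N haplotypes and bubble extraction.

Two complementary anchor finders are provided:

* :func:`find_multi_mum` — exact: the longest substring occurring exactly
  once in every haplotype interval, found through a generalized suffix
  array over the concatenated intervals.  Used on small intervals and as
  the reference semantics.
* :func:`anchor_chromosome` — scalable: seeds are k-mers (k = minimum
  anchor length) that are unique within every haplotype's current interval
  and identical across haplotypes; consecutive seeds merge into maximal
  runs, runs are chained colinearly, and the recursion descends into the
  gaps between accepted anchors until no further anchor is found.

Any k-mer inside an accepted anchor is unique per interval, so anchors
satisfy the exactly-once invariant by construction.  Anchoring is
strand-fixed: reverse-complement matches are left to the rearrangement
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from svscape.core import Anchor, AssemblySet, Bubble

_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit-packed k-mer codes (k <= 31); windows containing an
    ambiguous base get -1 and never seed an anchor."""
    if k > 31:
        raise ValueError("k must be <= 31 for exact packing")
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        c = codes[j : j + m]
        h = (h << 2) | np.where(c < 4, c, 0)
        bad |= c >= 4
    h[bad] = -1
    return h


# --------------------------------------------------------------------------
# exact multi-MUM through a generalized suffix array
# --------------------------------------------------------------------------


def _suffix_array(arr: np.ndarray) -> np.ndarray:
    n = arr.size
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            rank2[: n - k] = rank[k:]
        sa = np.lexsort((rank2, rank))
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (rank[sa[1:]] != rank[sa[:-1]]) | (
            rank2[sa[1:]] != rank2[sa[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def _lcp_array(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = LCP(suffix sa[i-1], suffix sa[i])."""
    n = arr.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    a = arr
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and a[i + h] == a[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def find_multi_mum(intervals: list[str], min_len: int = 20) -> Anchor | None:
    """Longest substring occurring exactly once in every interval (identical
    in all); ``None`` if no such match of at least ``min_len`` exists.
    Ties break to the leftmost start in the first (reference) interval."""
    n_doc = len(intervals)
    if any(len(s) == 0 for s in intervals):
        raise ValueError("all intervals must be non-empty")
    pieces, docs, pos_in_doc = [], [], []
    for d, s in enumerate(intervals):
        codes = encode(s)
        pieces.append(codes)
        pieces.append(np.array([5 + d], dtype=np.int64))  # unique sentinel per doc
        docs.append(np.full(codes.size + 1, d, dtype=np.int64))
        pos_in_doc.append(np.arange(codes.size + 1, dtype=np.int64))
    arr = np.concatenate(pieces)
    doc_of = np.concatenate(docs)
    pos_of = np.concatenate(pos_in_doc)
    sa = _suffix_array(arr)
    lcp = _lcp_array(arr, sa)
    n = arr.size
    if n < n_doc:
        return None

    sa_docs = doc_of[sa]
    win_docs = np.lib.stride_tricks.sliding_window_view(sa_docs, n_doc)
    distinct = (np.sort(win_docs, axis=1) == np.arange(n_doc)).all(axis=1)

    # candidate length per window = min of internal LCPs
    if n_doc >= 2:
        internal = np.lib.stride_tricks.sliding_window_view(lcp[1:], n_doc - 1).min(
            axis=1
        )
        internal = internal[: n - n_doc + 1]
    else:
        internal = np.full(n, np.iinfo(np.int64).max)[: n - n_doc + 1]
    left = lcp[: n - n_doc + 1]
    right = np.zeros(n - n_doc + 1, dtype=np.int64)
    right[: n - n_doc] = lcp[n_doc:]
    boundary = np.maximum(left, right)
    valid = distinct & (internal >= min_len) & (internal > boundary)
    if not valid.any():
        return None
    best_len = internal[valid].max()
    best_windows = np.nonzero(valid & (internal == best_len))[0]
    # leftmost start on the reference among best windows
    best_i, best_ref = None, None
    for i in best_windows:
        window = sa[i : i + n_doc]
        ref_pos = int(pos_of[window[np.nonzero(doc_of[window] == 0)[0][0]]])
        if best_ref is None or ref_pos < best_ref:
            best_ref, best_i = ref_pos, int(i)
    window = sa[best_i : best_i + n_doc]
    starts = [0] * n_doc
    for p in window:
        starts[int(doc_of[p])] = int(pos_of[p])
    return Anchor(length=int(best_len), starts=tuple(starts))


# --------------------------------------------------------------------------
# scalable chained anchoring
# --------------------------------------------------------------------------


def _unique_once(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted values occurring exactly once, their positions)."""
    order = np.argsort(values, kind="stable")
    sv = values[order]
    if sv.size == 0:
        return sv, order
    boundary = np.ones(sv.size + 1, dtype=bool)
    boundary[1:-1] = sv[1:] != sv[:-1]
    starts = np.nonzero(boundary[:-1])[0]
    counts = np.diff(np.nonzero(boundary)[0])
    once = counts == 1
    return sv[starts[once]], order[starts[once]]


def _shared_unique_runs(
    hashes: list[np.ndarray],
    intervals: list[tuple[int, int]],
    k: int,
) -> list[tuple[int, np.ndarray]]:
    """Maximal runs of k-mers unique within every haplotype interval and
    identical across haplotypes; returns (length, absolute starts) tuples."""
    n_hap = len(hashes)
    vals, poss = [], []
    for h in range(n_hap):
        s, e = intervals[h]
        hi = min(e - k + 1, hashes[h].size)
        if hi <= s:
            return []
        sl = hashes[h][s:hi]
        v, p = _unique_once(sl)
        good = v >= 0
        vals.append(v[good])
        poss.append(p[good] + s)
    shared = vals[0]
    for h in range(1, n_hap):
        shared = shared[np.isin(shared, vals[h], assume_unique=True)]
    if shared.size == 0:
        return []
    mat = np.empty((n_hap, shared.size), dtype=np.int64)
    for h in range(n_hap):
        idx = np.searchsorted(vals[h], shared)
        mat[h] = poss[h][idx]
    order = np.argsort(mat[0], kind="stable")
    mat = mat[:, order]
    if mat.shape[1] == 1:
        return [(k, mat[:, 0].copy())]
    consecutive = (np.diff(mat, axis=1) == 1).all(axis=0)
    runs = []
    start = 0
    for i in range(consecutive.size + 1):
        if i == consecutive.size or not consecutive[i]:
            run_len = i - start + 1
            runs.append((run_len + k - 1, mat[:, start].copy()))
            start = i + 1
    return runs


def _lis_filter(runs: list[tuple[int, np.ndarray]]) -> list[tuple[int, np.ndarray]]:
    """Keep a mutually colinear subset: successive strict longest-increasing
    subsequences along each non-reference haplotype's coordinate."""
    if len(runs) <= 1:
        return runs
    runs = sorted(runs, key=lambda r: int(r[1][0]))
    n_hap = runs[0][1].size
    keep = runs
    for axis in range(1, n_hap):
        seq = [int(r[1][axis]) for r in keep]
        idx = _lis_indices(seq)
        keep = [keep[i] for i in idx]
    return keep


def _lis_indices(seq: list[int]) -> list[int]:
    import bisect as _bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(seq)
    for i, x in enumerate(seq):
        j = _bisect.bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _verify_and_trim(
    runs: list[tuple[int, np.ndarray]], seqs: list[str]
) -> list[Anchor]:
    """Order anchors, trim overlaps between neighbors (exact matches stay
    exact under trimming), and verify sequence identity across haplotypes."""
    anchors: list[Anchor] = []
    prev_end: np.ndarray | None = None
    for length, starts in runs:
        starts = starts.copy()
        if prev_end is not None:
            overlap = int((prev_end - starts).max())
            if overlap > 0:
                starts += overlap
                length -= overlap
        if length <= 0:
            continue
        ref = seqs[0][starts[0] : starts[0] + length]
        if any(
            seqs[h][starts[h] : starts[h] + length] != ref for h in range(1, len(seqs))
        ):
            continue
        anchors.append(Anchor(length=int(length), starts=tuple(int(s) for s in starts)))
        prev_end = starts + length
    return anchors


def anchor_chromosome(
    seqs: list[str], min_anchor_length: int = 20, _max_depth: int = 30
) -> list[Anchor]:
    """Mutually colinear anchors across all haplotype sequences of one
    chromosome, found by seeded chaining plus recursion into the gaps."""
    if any(len(s) == 0 for s in seqs):
        raise ValueError("all haplotype sequences must be non-empty")
    k = min(min_anchor_length, 31)
    hashes = [kmer_hashes(encode(s), k) for s in seqs]
    n_hap = len(seqs)

    def _recurse(intervals: list[tuple[int, int]], depth: int) -> list[Anchor]:
        if depth > _max_depth:
            return []
        if any(e - s < k for s, e in intervals):
            return []
        runs = _shared_unique_runs(hashes, intervals, k)
        runs = [r for r in runs if r[0] >= min_anchor_length]
        if not runs:
            return []
        chained = _lis_filter(runs)
        accepted = _verify_and_trim(chained, seqs)
        if not accepted:
            return []
        out: list[Anchor] = []
        prev = [s for s, _ in intervals]
        for a in accepted:
            gap = [(prev[h], a.starts[h]) for h in range(n_hap)]
            if all(e > s for s, e in gap):
                out.extend(_recurse(gap, depth + 1))
            out.append(a)
            prev = [a.starts[h] + a.length for h in range(n_hap)]
        tail = [(prev[h], intervals[h][1]) for h in range(n_hap)]
        if all(e > s for s, e in tail):
            out.extend(_recurse(tail, depth + 1))
        return out

    anchors = _recurse([(0, len(s)) for s in seqs], 0)
    # final overlap pass across recursion boundaries
    runs = [(a.length, np.array(a.starts, dtype=np.int64)) for a in anchors]
    return _verify_and_trim(runs, seqs)


# --------------------------------------------------------------------------
# bubbles
# --------------------------------------------------------------------------


def decompose(
    anchors: list[Anchor], seqs: list[str]
) -> list[tuple[str, list[str] | None]]:
    """Alternating (kind, parts) decomposition: 'anchor' entries carry the
    shared substring, 'gap' entries one substring per haplotype.  Joining
    each haplotype's parts in order reconstructs its sequence exactly."""
    n_hap = len(seqs)
    out: list[tuple[str, list[str] | None]] = []
    prev = [0] * n_hap
    for a in anchors:
        gap = [seqs[h][prev[h] : a.starts[h]] for h in range(n_hap)]
        out.append(("gap", gap))
        out.append(("anchor", [seqs[0][a.starts[0] : a.starts[0] + a.length]]))
        prev = [a.starts[h] + a.length for h in range(n_hap)]
    out.append(("gap", [seqs[h][prev[h] :] for h in range(n_hap)]))
    return out


def extract_bubbles(
    anchors: list[Anchor],
    seqs: list[str],
    chrom: str,
    align_cap: int = 10_000,
    spanned: tuple[bool, ...] | None = None,
) -> list[Bubble]:
    """One bubble per inter-anchor gap where any two alleles differ.
    Bubbles whose longest allele exceeds ``align_cap`` are emitted with
    ``aligned=False`` (they still count as candidate SV loci)."""
    n_hap = len(seqs)
    if spanned is None:
        spanned = tuple(True for _ in range(n_hap))
    bubbles: list[Bubble] = []
    prev = [0] * n_hap
    bounds = [(a.starts, a.length) for a in anchors]
    for i in range(len(bounds) + 1):
        if i < len(bounds):
            nxt = list(bounds[i][0])
        else:
            nxt = [len(s) for s in seqs]
        alleles = [seqs[h][prev[h] : nxt[h]] for h in range(n_hap)]
        if len(set(alleles)) > 1:
            bubbles.append(
                Bubble(
                    chrom=chrom,
                    ref_start=prev[0],
                    ref_end=nxt[0],
                    alleles=alleles,
                    spanned=spanned,
                    aligned=max(len(a) for a in alleles) <= align_cap,
                    left_anchor=i - 1,
                    right_anchor=i if i < len(bounds) else -1,
                )
            )
        if i < len(bounds):
            prev = [bounds[i][0][h] + bounds[i][1] for h in range(n_hap)]
    return bubbles


def anchor_assembly(
    assembly: AssemblySet,
    min_anchor_length: int = 20,
    align_cap: int = 10_000,
) -> dict[str, tuple[list[Anchor], list[Bubble]]]:
    """Anchor every reference chromosome across the haplotypes that carry
    it; haplotypes missing a chromosome are unspanned there."""
    out: dict[str, tuple[list[Anchor], list[Bubble]]] = {}
    n_hap = assembly.n_haplotypes
    for chrom in assembly.chromosomes:
        present = [h for h in range(n_hap) if assembly.get(h, chrom)]
        seqs = [assembly.get(h, chrom) for h in present]
        anchors = anchor_chromosome(seqs, min_anchor_length)
        spanned = tuple(h in present for h in range(n_hap))
        bubbles = extract_bubbles(anchors, seqs, chrom, align_cap, spanned=None)
        # re-express bubbles over all haplotypes, marking missing ones
        if len(present) != n_hap:
            for b in bubbles:
                alleles = [""] * n_hap
                for i, h in enumerate(present):
                    alleles[h] = b.alleles[i]
                b.alleles = alleles
                b.spanned = spanned
        out[chrom] = (anchors, bubbles)
    return out
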