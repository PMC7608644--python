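"""Probabilistic consistency-based multiple alignment of bubble alleles
with per-column confidence, and confidence-thresholded segmentation into
variant loci.

The machinery follows the ProbCons recipe: pair-HMM forward-backward
posteriors for every sequence pair, a consistency transformation that
re-estimates each pairwise posterior through all third sequences (with
identity self-posteriors), a UPGMA guide tree over expected pairwise
accuracies, and progressive profile merging by maximum-expected-accuracy
dynamic programming.  Column confidence is defined for gap-bearing columns
too: a residue paired with a gapped row contributes that residue's
posterior probability of being unaligned in that pair, and two gapped rows
contribute 1.  Alignment columns that are confident (>= the threshold),
gap-free and unanimous delimit variant loci; every maximal run of the
remaining columns is one locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from svscape.config import PairHmmParams, PipelineConfig
from svscape.core import Bubble, VariantLocus
from svscape._kernels import mea_align, pair_forward_backward

_CODE5 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGTN"):
    _CODE5[_b] = _i
    _CODE5[_b + 32] = _i

_DENSE_LIMIT = 65_536  # cells; larger posterior matrices go sparse


def _encode(seq: str, what: str = "sequence") -> np.ndarray:
    codes = _CODE5[np.frombuffer(seq.encode(), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        raise ValueError(
            f"invalid base {seq[bad[0]]!r} at position {int(bad[0])} in {what}"
        )
    return codes


def _padded_emissions(params: PairHmmParams) -> tuple[np.ndarray, np.ndarray]:
    """Emissions extended with an N row/column (uniform over bases)."""
    em_m = np.full((5, 5), 1.0 / 16.0)
    em_m[:4, :4] = params.match_emission
    em_i = np.full(5, 0.25)
    em_i[:4] = params.insert_emission
    return em_m, em_i


def pair_posteriors(x: str, y: str, params: PairHmmParams) -> np.ndarray:
    """Dense posterior matrix P(x_i ~ y_j); rows of an empty pairing are
    all-zero, i.e. the partner positions are unaligned with probability 1."""
    xc = _encode(x, "sequence x")
    yc = _encode(y, "sequence y")
    if xc.size == 0 or yc.size == 0:
        return np.zeros((xc.size, yc.size))
    post, _ = pair_forward_backward(
        xc, yc, params.transitions, params.initial, *_padded_emissions(params)
    )
    return post


@dataclass
class PosteriorSet:
    """All pairwise posterior matrices for one bubble's alleles.

    ``mats[(i, j)]`` (i < j) is dense for small problems and CSR above
    ``_DENSE_LIMIT`` cells with sub-cutoff entries dropped (rows rescaled to
    preserve their mass)."""

    lengths: list[int]
    mats: dict[tuple[int, int], np.ndarray | sparse.csr_matrix]

    @property
    def n(self) -> int:
        return len(self.lengths)

    def get(self, i: int, j: int):
        if i < j:
            return self.mats[(i, j)]
        m = self.mats[(j, i)]
        return m.T.tocsr() if sparse.issparse(m) else m.T

    def row_sums(self, i: int, j: int) -> np.ndarray:
        m = self.get(i, j)
        s = np.asarray(m.sum(axis=1)).ravel()
        return s

    def gap_posterior(self, i: int, j: int) -> np.ndarray:
        """P(position of sequence i unaligned in the (i, j) pair)."""
        return np.clip(1.0 - self.row_sums(i, j), 0.0, 1.0)


def _maybe_sparsify(mat: np.ndarray, cutoff: float):
    if mat.size <= _DENSE_LIMIT:
        return mat
    rowsum = mat.sum(axis=1)
    mat = np.where(mat >= cutoff, mat, 0.0)
    kept = mat.sum(axis=1)
    scale = np.divide(rowsum, kept, out=np.ones_like(rowsum), where=kept > 0)
    mat *= scale[:, None]
    return sparse.csr_matrix(mat)


def compute_posteriors(
    alleles: list[str], params: PairHmmParams, cutoff: float = 1e-4
) -> PosteriorSet:
    mats = {}
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            mats[(i, j)] = _maybe_sparsify(
                pair_posteriors(alleles[i], alleles[j], params), cutoff
            )
    return PosteriorSet(lengths=[len(a) for a in alleles], mats=mats)


def consistency_transform(
    pset: PosteriorSet, n_rounds: int = 2, cutoff: float = 1e-4
) -> PosteriorSet:
    """ProbCons consistency re-estimation through all third sequences,
    including x and y themselves with identity self-posteriors:

        P'(x~y) = (1/K) [ 2 P(x~y) + sum_{z != x,y} P(x~z) P(z~y) ]
    """
    K = pset.n
    current = pset
    for _ in range(n_rounds):
        new_mats = {}
        for (i, j), mat in current.mats.items():
            acc = 2.0 * (mat.astype(np.float64) if not sparse.issparse(mat) else mat)
            for z in range(K):
                if z in (i, j):
                    continue
                if current.lengths[z] == 0:
                    continue
                a = current.get(i, z)
                b = current.get(z, j)
                acc = acc + a @ b
            acc = acc / K
            if sparse.issparse(acc):
                acc = np.asarray(acc.todense())
            new_mats[(i, j)] = _maybe_sparsify(np.asarray(acc), cutoff)
        current = PosteriorSet(lengths=list(current.lengths), mats=new_mats)
    return current


# --------------------------------------------------------------------------
# progressive alignment
# --------------------------------------------------------------------------


def expected_accuracy(pset: PosteriorSet, i: int, j: int) -> float:
    """Expected fraction of correctly aligned positions under the MEA
    alignment of the pair (ProbCons' guide-tree distance)."""
    ni, nj = pset.lengths[i], pset.lengths[j]
    if ni == 0 or nj == 0:
        return 0.0
    m = pset.get(i, j)
    dense = np.asarray(m.todense()) if sparse.issparse(m) else m
    _, score = mea_align(np.ascontiguousarray(dense))
    return float(score / min(ni, nj))


def _upgma_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA merge order on a distance matrix; ties break to the pair with
    the smallest indices (input order)."""
    n = dist.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best, best_pair = None, None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                v = d[(min(i, j), max(i, j))]
                if best is None or v < best - 1e-15:
                    best, best_pair = v, (i, j)
        i, j = best_pair
        merges.append((i, j))
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return merges


@dataclass
class MsaWithConfidence:
    """Aligned rows (gap character '-') plus per-column confidence."""

    rows: list[str]
    confidence: np.ndarray

    def ungapped(self, r: int) -> str:
        return self.rows[r].replace("-", "")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _pair_score_matrix(pset: PosteriorSet, rows_a, cols_a, rows_b, cols_b):
    """Summed posterior scores between two profiles' columns."""
    La, Lb = cols_a.shape[1], cols_b.shape[1]
    S = np.zeros((La, Lb))
    for ra, pa in zip(rows_a, cols_a):
        for rb, pb in zip(rows_b, cols_b):
            m = pset.get(ra, rb)
            dense = np.asarray(m.todense()) if sparse.issparse(m) else m
            if dense.size == 0:
                continue
            mask_a = pa >= 0
            mask_b = pb >= 0
            sub = dense[np.ix_(pa[mask_a], pb[mask_b])]
            S[np.ix_(mask_a, mask_b)] += sub
    return S


def progressive_align(alleles: list[str], pset: PosteriorSet) -> MsaWithConfidence:
    """UPGMA-guided profile merging by maximum expected accuracy; returns
    the MSA (rows in input order) with per-column confidence."""
    n = len(alleles)
    if n == 1:
        return MsaWithConfidence(rows=[alleles[0]], confidence=np.ones(len(alleles[0])))
    acc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc[i, j] = acc[j, i] = expected_accuracy(pset, i, j)
    merges = _upgma_order(1.0 - acc)

    # profile: (row indices, column position matrix with -1 for gaps)
    profiles: dict[int, tuple[list[int], np.ndarray]] = {
        i: ([i], np.arange(len(alleles[i]), dtype=np.int64)[None, :]) for i in range(n)
    }
    next_id = n
    for i, j in merges:
        rows_a, cols_a = profiles.pop(i)
        rows_b, cols_b = profiles.pop(j)
        if cols_a.shape[1] == 0 or cols_b.shape[1] == 0:
            # trivial merge with an empty profile
            if cols_a.shape[1] == 0:
                rows, cols = (
                    rows_a + rows_b,
                    np.vstack(
                        [np.full((len(rows_a), cols_b.shape[1]), -1, np.int64), cols_b]
                    ),
                )
            else:
                rows, cols = (
                    rows_a + rows_b,
                    np.vstack(
                        [cols_a, np.full((len(rows_b), cols_a.shape[1]), -1, np.int64)]
                    ),
                )
        else:
            S = _pair_score_matrix(pset, rows_a, cols_a, rows_b, cols_b)
            moves, _ = mea_align(np.ascontiguousarray(S))
            L = moves.size
            cols = np.full((len(rows_a) + len(rows_b), L), -1, dtype=np.int64)
            ia = ib = 0
            for c, mv in enumerate(moves):
                if mv in (0, 1):
                    cols[: len(rows_a), c] = cols_a[:, ia]
                    ia += 1
                if mv in (0, 2):
                    cols[len(rows_a) :, c] = cols_b[:, ib]
                    ib += 1
            rows = rows_a + rows_b
        profiles[next_id] = (rows, cols)
        next_id += 1

    (rows, cols) = profiles.popitem()[1]
    order = np.argsort(np.array(rows))
    rows = [rows[k] for k in order]
    cols = cols[order]
    msa_rows = []
    for r, pos in zip(rows, cols):
        seq = alleles[r]
        msa_rows.append("".join(seq[p] if p >= 0 else "-" for p in pos))
    conf = column_confidence(cols, pset)
    return MsaWithConfidence(rows=msa_rows, confidence=conf)


def column_confidence(cols: np.ndarray, pset: PosteriorSet) -> np.ndarray:
    """Mean pairwise support per column: residue-residue pairs contribute
    the consistency-transformed match posterior, residue-gap pairs the
    residue's posterior of being unaligned in that pair, gap-gap pairs 1."""
    n, L = cols.shape
    if L == 0:
        return np.zeros(0)
    total = np.zeros(L)
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            m = pset.get(i, j)
            dense = np.asarray(m.todense()) if sparse.issparse(m) else m
            gap_i = np.clip(1.0 - dense.sum(axis=1), 0.0, 1.0) if dense.size else None
            gap_j = np.clip(1.0 - dense.sum(axis=0), 0.0, 1.0) if dense.size else None
            pi, pj = cols[i], cols[j]
            both = (pi >= 0) & (pj >= 0)
            only_i = (pi >= 0) & (pj < 0)
            only_j = (pi < 0) & (pj >= 0)
            neither = (pi < 0) & (pj < 0)
            contrib = np.zeros(L)
            if dense.size:
                contrib[both] = dense[pi[both], pj[both]]
                contrib[only_i] = gap_i[pi[only_i]]
                contrib[only_j] = gap_j[pj[only_j]]
            else:
                # one sequence is empty: any residue is unaligned for sure
                contrib[both | only_i | only_j] = 1.0
            contrib[neither] = 1.0
            total += contrib
    return total / n_pairs


# --------------------------------------------------------------------------
# segmentation into variant loci
# --------------------------------------------------------------------------


def segment_variants(
    msa: MsaWithConfidence, threshold: float = 0.99
) -> list[tuple[int, int, list[str]]]:
    """Delimit variant loci by confident, gap-free, unanimous columns.

    Such columns are the merged (invariant) graph nodes; every maximal run
    of the remaining columns is a variant locus.  Returned tuples are
    (reference offset start, reference offset end, per-row alleles), with
    offsets counted in ungapped reference (row 0) positions from the start
    of the alignment.
    """
    L = msa.n_columns
    if L == 0:
        return []
    rows = msa.rows
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), L)
    gapless = (arr != ord("-")).all(axis=0)
    unanimous = (arr == arr[0]).all(axis=0)
    boundary = (msa.confidence >= threshold) & gapless & unanimous
    ref_res = (arr[0] != ord("-")).astype(np.int64)
    ref_before = np.concatenate([[0], np.cumsum(ref_res)])  # ref offset before col

    loci = []
    c = 0
    while c < L:
        if boundary[c]:
            c += 1
            continue
        start = c
        while c < L and not boundary[c]:
            c += 1
        alleles = [
            row[start:c].replace("-", "") for row in rows
        ]
        loci.append((int(ref_before[start]), int(ref_before[c]), alleles))
    return loci


# --------------------------------------------------------------------------
# bubble-level driver
# --------------------------------------------------------------------------


def _block_msa(alleles: list[str]) -> MsaWithConfidence:
    """Fallback layout for bubbles too large for full posterior DP: alleles
    are stacked block-diagonally with zero column confidence, so the whole
    bubble remains one unsplit variant locus."""
    total = sum(len(a) for a in alleles)
    rows = []
    offset = 0
    for a in alleles:
        rows.append("-" * offset + a + "-" * (total - offset - len(a)))
        offset += len(a)
    return MsaWithConfidence(rows=rows, confidence=np.zeros(total))


def align_bubble(
    alleles: list[str], cfg: PipelineConfig
) -> MsaWithConfidence:
    """Full consistency MSA for bubbles whose longest allele fits the DP
    cap; block layout (zero confidence) beyond it."""
    if max(len(a) for a in alleles) > cfg.full_dp_cap:
        return _block_msa(alleles)
    pset = compute_posteriors(alleles, cfg.hmm, cfg.sparse_cutoff)
    pset = consistency_transform(pset, cfg.consistency_rounds, cfg.sparse_cutoff)
    return progressive_align(alleles, pset)


def bubble_to_loci(bubble: Bubble, cfg: PipelineConfig) -> list[VariantLocus]:
    """Variant loci of one bubble, in reference coordinates."""
    if not bubble.aligned:
        return [
            VariantLocus(
                chrom=bubble.chrom,
                start=bubble.ref_start,
                end=bubble.ref_end,
                alleles=list(bubble.alleles),
                spanned=bubble.spanned,
            )
        ]
    msa = align_bubble(bubble.alleles, cfg)
    loci = []
    for off_start, off_end, alleles in segment_variants(msa, cfg.column_conf_threshold):
        loci.append(
            VariantLocus(
                chrom=bubble.chrom,
                start=bubble.ref_start + off_start,
                end=bubble.ref_start + off_end,
                alleles=alleles,
                spanned=bubble.spanned,
            )
        )
    return loci
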