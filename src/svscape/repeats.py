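"""SV classification: mobile-element insertions, VNTRs, and the rest.

Tandem repeats are found with a simplified Tandem-Repeat-Finder scheme:
candidate periods come from exact k-mer re-occurrence distances (a period
survives when at least ``match_prob``% of the tuples at that distance
match), a consensus is built by phase-wise majority, and the candidate is
scored by local wraparound dynamic programming with the classic weights
(match +2, mismatch -7, indel -7, min score 20, max period 500).  Short
alleles are scanned exhaustively over all periods instead.

Classification order is MEI first, then VNTR, then other.  The MEI test
compares each variable allele (the difference sequence after stripping the
common flanks) against the element library by local alignment, requiring
80% reciprocal coverage and 80% identity.  The VNTR test requires the best
repeat of some allele to span strictly more than half of that allele, or
the locus to intersect the reference tandem-repeat track (which captures
single-unit indels whose allele is itself non-repetitive).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio import Align

from svscape.config import PipelineConfig, TrfWeights
from svscape.core import SvClass, SvLocus, TandemRepeat, gc_fraction, shannon_entropy
from svscape._kernels import wraparound_local

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_EXHAUSTIVE_LEN = 200  # below this, try every period instead of k-mer candidates
_CANDIDATE_K = 5
_MIN_COPIES = 1.9


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _candidate_periods(seq: str, weights: TrfWeights) -> list[int]:
    """Periods suggested by exact k-mer re-occurrence, filtered by the
    tuple-match probability: a distance survives when >= match_prob% of the
    k-tuples between its first and last re-occurrence match at that lag."""
    n = len(seq)
    max_p = min(weights.max_period, n)
    if n <= _EXHAUSTIVE_LEN:
        return list(range(1, max_p + 1))
    k = _CANDIDATE_K
    codes = _codes(seq)
    # distances between consecutive occurrences of each k-mer
    packed = np.zeros(n - k + 1, dtype=np.int64)
    for off in range(k):
        packed = packed * 5 + codes[off : off + n - k + 1]
    last_seen: dict[int, int] = {}
    dist_positions: dict[int, list[int]] = {}
    for i, h in enumerate(packed):
        h = int(h)
        if h in last_seen:
            d = i - last_seen[h]
            if 1 <= d <= max_p:
                dist_positions.setdefault(d, []).append(last_seen[h])
        last_seen[h] = i
    survivors = []
    thresh = weights.match_prob / 100.0
    for d, positions in dist_positions.items():
        if len(positions) < 2 and d > k:
            continue
        lo, hi = positions[0], positions[-1]
        span = hi - lo + 1
        idx = np.arange(lo, min(hi + 1, n - k - d + 1))
        if idx.size == 0:
            continue
        matches = 0
        for off in range(k):
            matches += int(np.count_nonzero(codes[idx + off] == codes[idx + off + d]))
        frac = matches / (idx.size * k)
        if frac >= thresh and span + d >= _MIN_COPIES * d:
            survivors.append(d)
    # tiny periods are cheap and easily missed by the k-mer histogram
    survivors.extend(range(1, min(k, max_p) + 1))
    return sorted(set(survivors))


def _phase_consensus(seq: str, period: int, window: tuple[int, int] | None = None) -> str:
    """Column-wise majority over period-phased positions; ties go to the
    alphabetically smallest base."""
    lo, hi = window if window else (0, len(seq))
    counts = np.zeros((period, 4), dtype=np.int64)
    codes = _codes(seq[lo:hi])
    phases = (np.arange(codes.size) % period)
    valid = codes < 4
    np.add.at(counts, (phases[valid], codes[valid]), 1)
    # argmax returns the first (alphabetically smallest) maximum
    best = counts.argmax(axis=1)
    return "".join("ACGT"[b] for b in best)


def _primitive_period(cons: str, weights: TrfWeights) -> int:
    """Smallest divisor d of len(cons) such that cons is >= match_prob%
    identical to a tiling of its own d-phase majority unit; len(cons) when
    the consensus is already primitive."""
    p = len(cons)
    thresh = weights.match_prob / 100.0
    for d in range(1, p):
        if p % d:
            continue
        tile = _phase_consensus(cons, d)
        matches = sum(1 for i, c in enumerate(cons) if c == tile[i % d])
        if matches / p >= thresh:
            return d
    return p


def detect_tandem_repeat(
    allele: str, weights: TrfWeights | None = None
) -> TandemRepeat | None:
    """Best-scoring tandem repeat of one allele, or None when no candidate
    reaches the minimum score with >= 1.9 copies.  Ties break to the
    smaller period; a winner whose consensus is itself a tandem tiling of a
    smaller unit is collapsed to that primitive period."""
    weights = weights or TrfWeights()
    n = len(allele)
    if n == 0:
        return None
    seq_codes = _codes(allele)
    candidates = _candidate_periods(allele, weights)
    best: TandemRepeat | None = None
    for p in candidates:
        cons = _phase_consensus(allele, p)
        score, lo, hi = wraparound_local(
            seq_codes, _codes(cons), float(weights.match), float(weights.mismatch),
            float(weights.indel),
        )
        score = int(score)
        if score < weights.min_score:
            continue
        copies = (hi - lo) / p
        if copies < _MIN_COPIES:
            continue
        if best is None or score > best.score or (
            score == best.score and p < best.period
        ):
            tract = allele[lo:hi]
            best = TandemRepeat(
                period=p,
                consensus=cons,
                copies=copies,
                score=score,
                gc=gc_fraction(tract),
                entropy=shannon_entropy(tract),
                span_fraction=(hi - lo) / n,
                tract_start=lo,
                tract_end=hi,
            )
    if best is not None:
        d = _primitive_period(best.consensus, weights)
        if d < best.period:
            cons = _phase_consensus(allele, d)
            score, lo, hi = wraparound_local(
                seq_codes, _codes(cons), float(weights.match),
                float(weights.mismatch), float(weights.indel),
            )
            score = int(score)
            copies = (hi - lo) / d
            if score >= weights.min_score and copies >= _MIN_COPIES:
                tract = allele[lo:hi]
                best = TandemRepeat(
                    period=d,
                    consensus=cons,
                    copies=copies,
                    score=score,
                    gc=gc_fraction(tract),
                    entropy=shannon_entropy(tract),
                    span_fraction=(hi - lo) / n,
                    tract_start=lo,
                    tract_end=hi,
                )
    return best


# --------------------------------------------------------------------------
# mobile-element insertions
# --------------------------------------------------------------------------


def variable_alleles(alleles: Sequence[str], spanned: Sequence[bool]) -> list[str]:
    """Difference sequences of each longer allele against the shortest
    spanned allele, after stripping the longest common prefix and suffix."""
    present = [a for a, sp in zip(alleles, spanned) if sp]
    if not present:
        return []
    shortest = min(present, key=len)
    out = []
    for a in present:
        if a == shortest:
            continue
        pre = 0
        while pre < len(shortest) and pre < len(a) and shortest[pre] == a[pre]:
            pre += 1
        suf = 0
        while (
            suf < len(shortest) - pre
            and suf < len(a) - pre
            and shortest[-1 - suf] == a[-1 - suf]
        ):
            suf += 1
        diff = a[pre : len(a) - suf]
        if diff:
            out.append(diff)
    return out


def _make_aligner(weights: TrfWeights) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = weights.match
    aligner.mismatch_score = -weights.mismatch
    aligner.open_gap_score = -weights.indel
    aligner.extend_gap_score = -weights.indel
    return aligner


def classify_mei(
    sv: SvLocus,
    library: Sequence[tuple[str, str]],
    config: PipelineConfig,
) -> str | None:
    """Best-matching element family, or None.  A variable allele is an MEI
    when a library element aligns locally with >= 80% reciprocal coverage
    (of the allele and of the element) and >= 80% identity within the
    matched region."""
    if not library:
        return None
    aligner = _make_aligner(config.trf)
    frac = config.mei_reciprocal_overlap
    best_score, best_family = 0.0, None
    for diff in variable_alleles(sv.alleles, sv.spanned):
        la = len(diff)
        for family, element in library:
            le = len(element)
            # coverage is impossible when the lengths are too dissimilar
            if le < 0.6 * la or la < 0.6 * le:
                continue
            aln = aligner.align(diff, element)
            if len(aln) == 0:
                continue
            top = aln[0]
            blocks_a, blocks_e = top.aligned
            if len(blocks_a) == 0:
                continue
            span_a = int(blocks_a[-1][1] - blocks_a[0][0])
            span_e = int(blocks_e[-1][1] - blocks_e[0][0])
            if span_a < frac * la or span_e < frac * le:
                continue
            matches = 0
            for (a0, a1), (e0, e1) in zip(blocks_a, blocks_e):
                matches += sum(
                    1 for x, y in zip(diff[a0:a1], element[e0:e1]) if x == y
                )
            identity = matches / max(span_a, span_e)
            if identity < frac:
                continue
            if top.score > best_score:
                best_score, best_family = float(top.score), family
    return best_family


# --------------------------------------------------------------------------
# VNTRs
# --------------------------------------------------------------------------


def reference_repeat_track(
    reference: dict[str, str],
    loci: Sequence[SvLocus],
    config: PipelineConfig,
    pad: int = 100,
) -> list[tuple[str, int, int]]:
    """Tandem-repeat annotations of the reference sequence in the windows
    around the given loci (the track is only ever consulted at loci, so
    scanning near them is equivalent to annotating the whole genome)."""
    track = []
    seen = set()
    for sv in loci:
        seq = reference.get(sv.chrom)
        if seq is None:
            continue
        lo = max(0, sv.start - pad)
        hi = min(len(seq), sv.end + pad)
        key = (sv.chrom, lo, hi)
        if key in seen or hi <= lo:
            continue
        seen.add(key)
        rep = detect_tandem_repeat(seq[lo:hi], config.trf)
        if rep is not None:
            track.append((sv.chrom, lo + rep.tract_start, lo + rep.tract_end))
    return track


def classify_vntr(
    sv: SvLocus,
    reference_trf_track: Sequence[tuple[str, int, int]] | None,
    config: PipelineConfig,
) -> tuple[bool, TandemRepeat | None]:
    """VNTR decision plus the best repeat across alleles.  Ties between
    alleles break by (higher score, longer period, lower haplotype index)."""
    best: TandemRepeat | None = None
    spans_majority = False
    for a, sp in zip(sv.alleles, sv.spanned):
        if not sp or not a:
            continue
        rep = detect_tandem_repeat(a, config.trf)
        if rep is None:
            continue
        if rep.span_fraction > config.vntr_span_fraction:
            spans_majority = True
        if best is None or (rep.score, rep.period) > (best.score, best.period):
            best = rep
    in_track = False
    if reference_trf_track:
        for chrom, lo, hi in reference_trf_track:
            if chrom == sv.chrom and lo < max(sv.end, sv.start + 1) and hi > sv.start:
                in_track = True
                break
    return (spans_majority or in_track), best


def classify_all(
    svs: Sequence[SvLocus],
    library: Sequence[tuple[str, str]],
    reference_trf_track: Sequence[tuple[str, int, int]] | None,
    config: PipelineConfig,
) -> dict[str, float]:
    """Assign classes in place (MEI before VNTR before other) and return
    the class fractions over SVs; empty input reports no fractions."""
    n_sv = 0
    tallies: dict[str, int] = {}
    for sv in svs:
        if not sv.is_sv:
            continue
        n_sv += 1
        family = classify_mei(sv, library, config)
        if family is not None:
            sv.svclass = SvClass.MEI
            sv.mei_family = family
        else:
            is_vntr, rep = classify_vntr(sv, reference_trf_track, config)
            sv.repeat = rep
            sv.svclass = SvClass.VNTR if is_vntr else SvClass.OTHER
        tallies[sv.svclass.value] = tallies.get(sv.svclass.value, 0) + 1
    if n_sv == 0:
        return {}
    return {k: v / n_sv for k, v in sorted(tallies.items())}
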