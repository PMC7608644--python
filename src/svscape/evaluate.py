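"""Truth-set evaluation: match planted variants against called loci.

A planted variant counts as recovered when some called locus on the same
chromosome has (a) an allele-length range within ``range_tol`` bp of the
planted range and (b) boundaries within ``boundary_tol`` bp of either the
planted interval or its parsimony-trimmed representation.  Two acceptable
boundary representations exist because anchoring stops at the first unique
flanking k-mer (so a bubble approximates the planted window), while a fully
resolved alignment reports the minimal trimmed locus.

Planted inversions are length-balanced and therefore evaluated against the
inversion calls, not the SV set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from svscape.core import InversionCall, SvClass, SvLocus, TruthRecord, VariantClass

# expected SV class per planted class (inversions are handled separately;
# deletions are large non-repetitive events, i.e. "other")
EXPECTED_CLASS = {
    VariantClass.VNTR: SvClass.VNTR,
    VariantClass.MEI: SvClass.MEI,
    VariantClass.DEL: SvClass.OTHER,
}


@dataclass
class TruthMatch:
    truth: TruthRecord
    matched: bool
    call: SvLocus | InversionCall | None = None
    class_correct: bool | None = None


@dataclass
class RecoveryReport:
    matches: list[TruthMatch]
    n_truth: int
    n_recovered: int
    sub_threshold_called: int
    class_accuracy: float | None

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def _interval_close(
    start: int, end: int, t_start: int, t_end: int, tol: int
) -> bool:
    return abs(start - t_start) <= tol and abs(end - t_end) <= tol


def _boundary_ok(sv: SvLocus, t: TruthRecord, tol: int) -> bool:
    if _interval_close(sv.start, sv.end, t.start, t.end, tol):
        return True
    if t.trim_start >= 0 and _interval_close(
        sv.start, sv.end, t.trim_start, t.trim_end, tol
    ):
        return True
    return False


def match_truth(
    truth: Sequence[TruthRecord],
    svs: Sequence[SvLocus],
    inversions: Sequence[InversionCall] = (),
    boundary_tol: int = 20,
    range_tol: int = 2,
    inversion_tol: int = 20,
) -> RecoveryReport:
    """Match every planted variant to the call set and report recovery,
    sub-threshold false calls, and classification accuracy."""
    by_chrom: dict[str, list[SvLocus]] = {}
    for sv in svs:
        if sv.is_sv:
            by_chrom.setdefault(sv.chrom, []).append(sv)
    inv_by_chrom: dict[str, list[InversionCall]] = {}
    for c in inversions:
        inv_by_chrom.setdefault(c.chrom, []).append(c)

    matches: list[TruthMatch] = []
    n_truth = n_rec = sub_called = 0
    class_hits = class_total = 0
    for t in truth:
        if t.sub_threshold:
            # controls: must NOT appear as an SV at their position
            called = any(
                _boundary_ok(sv, t, boundary_tol) for sv in by_chrom.get(t.chrom, [])
            )
            sub_called += int(called)
            matches.append(TruthMatch(t, matched=not called))
            continue
        n_truth += 1
        if t.vclass is VariantClass.INV:
            hit = None
            for c in inv_by_chrom.get(t.chrom, []):
                if _interval_close(c.start, c.end, t.start, t.end, inversion_tol):
                    hit = c
                    break
            matches.append(TruthMatch(t, matched=hit is not None, call=hit))
            n_rec += int(hit is not None)
            continue
        hit = None
        for sv in by_chrom.get(t.chrom, []):
            if not _boundary_ok(sv, t, boundary_tol):
                continue
            if abs(sv.length_range - t.length_range) <= range_tol:
                hit = sv
                break
        matched = hit is not None
        n_rec += int(matched)
        class_ok = None
        expected = EXPECTED_CLASS.get(t.vclass)
        if matched and expected is not None:
            class_total += 1
            class_ok = hit.svclass is expected
            class_hits += int(class_ok)
        matches.append(TruthMatch(t, matched=matched, call=hit, class_correct=class_ok))
    return RecoveryReport(
        matches=matches,
        n_truth=n_truth,
        n_recovered=n_rec,
        sub_threshold_called=sub_called,
        class_accuracy=(class_hits / class_total) if class_total else None,
    )
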