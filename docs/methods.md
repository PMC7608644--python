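# Methods

All coordinates are 0-based, half-open inside the package; conversion to
1-based happens only at the VCF/GFF3 boundary. All randomness flows from the
single simulation seed; reruns reproduce every output byte for byte.

## Synthetic genome

The simulator draws a proto reference per chromosome (i.i.d. bases, GC 0.5;
subtelomeric blocks GC-skewed to 0.55), then derives the haplotypes by
substituting planted alleles and scattering background SNVs (rate 0.001).
Planted classes:

- **VNTR** — a non-homopolymer subunit (length and GC drawn per locus) tiled
  with per-haplotype copy numbers; planted arrays are guaranteed an
  allele-length range of at least 60 bp unless the locus is an explicit
  sub-threshold negative control (< 50 bp range).
- **MEI** — a copy of one of four library consensus elements (lengths 300,
  1800, 1300, 900 bp) inserted into a random carrier subset of haplotypes.
- **Deletion** — removal of a random 100–1500 bp reference window.
- **Inversion** — reverse complement of a 300–2000 bp window;
  length-balanced, hence invisible to the length-range SV definition and
  evaluated against the inversion caller instead.

Loci keep ≥ `min_locus_spacing` separation. VNTR positions honor a
configurable subtelomeric density fold. Truth records store the exact planted
interval, per-haplotype allele lengths, and the parsimony-trimmed
representation (longest common prefix/suffix of the planted alleles in their
sequence context), which is the minimal locus a boundary-exact caller should
report.

Gene models are toy GFF3 gene/mRNA/exon/CDS/UTR features; expression is drawn
through a Gaussian copula so that the Spearman correlation of gene length with
log10 mean brain TPM equals a configured target exactly in rank terms.

## Anchoring and bubbles

An anchor is a maximal exact match present exactly once in every haplotype's
current interval (strand-fixed). Anchors ≥ 20 bp are found recursively from
shared unique k-mers; the intervals between consecutive anchors form bubbles
with one allele per haplotype. Bubbles whose longest allele exceeds
`bubble_align_cap` (10 kb) are kept but flagged unaligned. Anchors plus
bubble alleles decompose each haplotype losslessly.

## Multiple alignment with column confidence

Allele pairs are aligned with a three-state pair-HMM (match emission 0.97
identity, gap open 0.02, mean gap length 3) by forward–backward, giving
posterior match probabilities. Probabilistic-consistency transformation
(two rounds, sparse matrices) re-estimates each pair's posteriors through
every third sequence; progressive alignment along a posterior-similarity
guide tree produces the MSA. Column confidence is the mean pairwise match
posterior of the column's residues; alleles longer than `full_dp_cap`
(2 kb) fall back to a block layout with zero confidence. A variant locus is
a maximal run of columns that fails `column_conf_threshold` (0.99), a gap in
any row, or non-unanimity; its alleles are the ungapped row slices.

## SV definition and set operations

A locus is an SV when the allele-length range over the haplotypes that span
it is ≥ 50 bp. Loci unspanned in some haplotype remain in the compendium but
are excluded from the fully-assessed set. An SV is unique to haplotype *h*
when removing *h* (and only *h*) brings the range below 50 bp. The
reference-detectable subset keeps SVs with some non-reference allele ≥ 50 bp
different in length from the reference allele; membership per haplotype uses
the same rule and partitions that subset across all non-empty haplotype
subsets. Interval set comparisons use ≥ 1 bp overlap by default or an
optional reciprocal-fraction requirement; zero-length insertion points are
widened to 1 bp.

## Classification

MEI first: each variable allele (difference sequence after stripping common
flanks against the shortest spanned allele) is locally aligned against the
library; a hit needs ≥ 80% coverage of both the allele and the element and
≥ 80% identity within the matched region. Otherwise VNTR: a simplified
Tandem-Repeats-Finder scan (k-mer re-occurrence candidate periods for long
alleles, exhaustive periods for short ones; phase-majority consensus; local
wraparound dynamic programming with match +2, mismatch −7, indel −7, minimum
score 20, ≥ 1.9 copies; ties to the smaller period; consensus collapsed to
its primitive period). An SV is a VNTR when the best repeat spans strictly
more than half of some allele, or when the locus intersects the reference
tandem-repeat track. Everything else is "other"; SVs overlapping an
inversion call are labeled inversion-associated.

## Rearrangement analysis

Per haplotype, unique exact matches against the reference (both strands) are
chained by a dynamic program maximizing matched length minus a per-breakpoint
penalty (default 2 × anchor length); colinear runs become oriented segments.
Query-adjacent segments form the breakpoint graph (GFA 1.0; edges carry
`BP:i:1` when the reference adjacency is non-colinear). An inversion is
called for each query-consecutive triple (A, B, C) from one contig where B's
orientation opposes both flanks, both flanks are strictly larger, all three
share a chromosome, and the three are consecutive on the reference axis.
Calls inside a VNTR locus are flagged ambiguous, not dropped. Diploid pairs
merge into homozygous calls at ≥ 50% reciprocal overlap.

## Landscape statistics

The subtelomere mask covers the terminal `subtelomere_span` of every
non-acrocentric arm; the assessable mask removes bubbles unspanned in some
haplotype. Density folds are counts per assessable megabase inside versus
outside the mask, for all SVs, VNTRs, and GC-/pattern-filtered VNTRs
(repeat GC strictly > 0.6 and period strictly > 15). P-values come from
seeded permutations placing the same number of loci uniformly over the
assessable mask. Expansion bias tabulates, over fully-assessed SVs, how
often haplotype *x*'s allele is ≥ 50 bp shorter than haplotype *y*'s, plus
per-haplotype allele-length z-scores. Genic regions are assigned with
CDS > UTR > intron > intergenic precedence (pure insertions use their
insertion point). Gene-level VNTR counts (any VNTR overlapping the gene
body) and gene length are each rank-correlated (Spearman, average ranks on
ties) with log10 mean brain TPM; genes absent from the expression table are
excluded and listed.

## Evaluation

A planted variant is recovered when a called SV on the same chromosome
matches its allele-length range within 2 bp and its boundaries within 20 bp
of either the planted interval or its parsimony-trimmed representation.
Inversions are matched against inversion calls within 20 bp. Sub-threshold
controls must not be called. Classification accuracy is scored over matched
calls with VNTR → VNTR, MEI → MEI, deletion → other.
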