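# svscape

A self-contained pipeline that builds a multi-haplotype structural-variant
(SV) compendium from assembled haplotype sequences and characterizes the
resulting variant landscape. Because fully assembled real genomes are large,
the package ships a seeded simulator that generates a toy multi-chromosome,
multi-haplotype genome with known planted variants, so every downstream
statistic can be checked against ground truth.

## What the pipeline does

1. **simulate** — generate a reference and derived haplotypes with planted
   VNTRs (variable-number tandem repeats), mobile-element insertions (MEIs),
   deletions and balanced inversions, plus toy gene models and a per-tissue
   expression table. Everything is reproducible from one seed.
2. **anchor / align** — find maximal exact matches unique in every haplotype,
   use them as anchors, and align the intervening "bubbles" with a pair-HMM
   consistency-transformed multiple alignment that carries per-column
   confidence scores.
3. **call** — segment low-confidence alignment runs into multi-allelic
   variant loci and promote loci whose allele-length range is ≥ 50 bp (over
   the haplotypes that span them) to SVs; flag haplotype-unique SVs, the
   reference-detectable subset, and its presence/absence partition across
   haplotypes.
4. **classify** — label each SV as MEI (80/80 reciprocal-coverage/identity
   local alignment against the element library), VNTR (a simplified
   Tandem-Repeats-Finder scan with wraparound dynamic programming), or other;
   MEI takes precedence over VNTR.
5. **rearrange** — chain unique exact matches per haplotype into oriented
   segments, emit a breakpoint graph (GFA), and call inversions as smaller
   opposite-orientation segments enclosed by consecutive flanks.
6. **landscape** — subtelomeric density folds with permutation p-values,
   per-haplotype expansion/contraction asymmetry, genic-region annotation,
   and gene-level VNTR burden versus expression correlations.

## Usage

One-shot, in memory:

```python
from svscape.config import demo_config
from svscape.pipeline import run_pipeline

result = run_pipeline(demo_config(seed=42), out_dir="results/run")
```

Stage by stage on a run directory of plain-text intermediates:

```
svscape simulate  --seed 42 --out-dir run/
svscape align     --out-dir run/
svscape call      --out-dir run/
svscape classify  --out-dir run/
svscape rearrange --out-dir run/
svscape landscape --out-dir run/
```

`svscape run-all` composes the stages (with `--resume` to skip completed
ones) and produces byte-identical outputs. Every threshold can be overridden
on the command line (e.g. `--sv-min-span 50 --column-conf-threshold 0.99`)
or through `--config config.json`.

Outputs per run: `compendium.tsv` (the SV table), `svs.vcf` (multi-allelic,
sequence-resolved), `segments.bed`, `breakpoints.gfa`, `inversions.tsv`,
`enrichment.tsv`, `expansion_smaller.tsv`, `genes.tsv`, `genes.gff3`,
`expression.tsv` and `manifest.json` (config echo, stage timings, sha256
digests of every output).

## Repository layout

- `src/svscape/` — the package (simulator, anchoring, alignment, calling,
  classification, rearrangement, landscape statistics, IO, CLI).
- `analysis/` — numbered drivers that run the demonstration study and write
  summary tables under `results/`.
- `scripts/acceptance.py` — runs the demonstration study at a given seed and
  reports the headline quantities as JSON:
  `python scripts/acceptance.py --seed 42 --out results/acceptance.json`.
- `tests/` — unit tests per module plus an acceptance suite in
  `tests/test_acceptance.py` that checks the main behaviors against
  independent brute-force oracles.
- `docs/methods.md` — method details and definitions.

## Testing

```
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

The suite includes two end-to-end pipeline runs (a small study and the
bundled 5 Mb demonstration study) and takes several minutes.
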