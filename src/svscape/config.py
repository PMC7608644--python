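"""Configuration objects for the simulator and the calling pipeline.

All coordinates are 0-based, half-open everywhere inside the package;
conversion to 1-based happens only at the VCF/GFF3 boundary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ChromosomeSpec:
    """A toy chromosome: name, length, centromere position and whether the
    short (p) arm is acrocentric (its subtelomere is excluded from masks)."""

    name: str
    length: int
    centromere: int
    acrocentric_p: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"chromosome {self.name}: centromere must lie inside the chromosome"
            )


@dataclass(frozen=True)
class VntrTruthParams:
    """How planted tandem-repeat arrays are drawn.

    Subunits are sampled with a per-repeat target GC by biased per-base
    sampling and are never homopolymers.  Copy numbers vary per haplotype;
    planted arrays are guaranteed an allele-length range of at least
    ``min_planted_range`` bp (comfortably above the 50 bp SV definition)
    unless the locus is an explicit sub-threshold negative control.
    """

    subunit_len_range: tuple[int, int] = (6, 60)
    gc_range: tuple[float, float] = (0.30, 0.80)
    copy_range: tuple[int, int] = (5, 25)
    copy_delta_sd: float = 3.0
    min_planted_range: int = 60


@dataclass(frozen=True)
class GeneParams:
    n_genes: int = 300
    length_range: tuple[int, int] = (2_000, 60_000)  # log-uniform
    exon_count_range: tuple[int, int] = (2, 8)


@dataclass(frozen=True)
class ExpressionParams:
    """Per-region expression table layout and the target monotone association
    between gene length and mean brain expression (Spearman scale)."""

    regions: tuple[str, ...] = (
        "brain_cortex",
        "brain_cerebellum",
        "brain_hippocampus",
        "brain_amygdala",
        "liver",
        "heart",
        "lung",
        "muscle",
    )
    brain_prefix: str = "brain"
    length_correlation: float = 0.5

    @property
    def brain_regions(self) -> tuple[str, ...]:
        return tuple(r for r in self.regions if r.startswith(self.brain_prefix))


#: toy mobile-element families: (family name, consensus length bp)
DEFAULT_MEI_LIBRARY: tuple[tuple[str, int], ...] = (
    ("Alu-like", 300),
    ("L1-like", 1800),
    ("SVA-like", 1300),
    ("ERV-like", 900),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the synthetic-genome generator needs; ``seed`` fixes all
    outputs bit-identically."""

    seed: int = 42
    n_haplotypes: int = 5
    chromosomes: tuple[ChromosomeSpec, ...] = ()
    subtelomere_span: int = 250_000
    n_vntr: int = 100
    n_mei: int = 50
    n_del: int = 30
    n_inv: int = 20
    n_subthreshold: int = 0
    subtelomeric_vntr_fold: float = 1.0
    vntr: VntrTruthParams = field(default_factory=VntrTruthParams)
    mei_library: tuple[tuple[str, int], ...] = DEFAULT_MEI_LIBRARY
    mei_family_weights: tuple[float, ...] = (0.85, 0.06, 0.06, 0.03)
    inversion_size_range: tuple[int, int] = (300, 2_000)
    deletion_size_range: tuple[int, int] = (100, 1_500)
    snv_rate: float = 0.001
    min_locus_spacing: int = 1_000
    subtelomere_gc: float = 0.55  # GC of subtelomeric reference blocks (rest: 0.50)
    gene: GeneParams = field(default_factory=GeneParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least a reference and one query haplotype")
        if self.subtelomere_span < 0 or self.subtelomeric_vntr_fold < 0:
            raise ValueError("subtelomere_span and subtelomeric_vntr_fold must be >= 0")
        for c in self.chromosomes:
            shortest_arm = min(c.centromere, c.length - c.centromere)
            if self.subtelomere_span > shortest_arm:
                raise ValueError(
                    f"subtelomere_span {self.subtelomere_span} exceeds the shortest "
                    f"arm of chromosome {c.name}"
                )
        if not -1.0 <= self.expression.length_correlation <= 1.0:
            raise ValueError("length_correlation must be in [-1, 1]")

    @property
    def total_planted(self) -> int:
        return self.n_vntr + self.n_mei + self.n_del + self.n_inv + self.n_subthreshold

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def demo_config(seed: int = 42) -> SimulationConfig:
    """The bundled demonstration study: a 5 Mb toy genome on two chromosomes,
    five haplotypes, 200 planted structural variants with >= 1 kb spacing."""
    return SimulationConfig(
        seed=seed,
        chromosomes=(
            ChromosomeSpec("chr1", 3_000_000, 1_400_000),
            ChromosomeSpec("chr2", 2_000_000, 700_000, acrocentric_p=True),
        ),
        subtelomere_span=250_000,
        n_vntr=100,
        n_mei=50,
        n_del=30,
        n_inv=20,
        subtelomeric_vntr_fold=5.0,
    )


# --------------------------------------------------------------------------
# pair-HMM parameters
# --------------------------------------------------------------------------

_BASES = "ACGT"


def _default_match_emission(p_match: float = 0.97) -> np.ndarray:
    e = np.full((4, 4), (1.0 - p_match) / 12.0)
    np.fill_diagonal(e, p_match / 4.0)
    return e


@dataclass(frozen=True)
class PairHmmParams:
    """Three-state (match / insert-x / insert-y) pair-HMM.

    The emission and transition values are package defaults tuned for
    nucleotide alleles (high match identity, mean gap length ~3 bp); they
    are configuration, not estimates, and can be overridden wholesale.
    """

    match_emission: np.ndarray = field(default_factory=_default_match_emission)
    insert_emission: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    delta: float = 0.02  # match -> insert (each of the two inserts)
    epsilon: float = 2.0 / 3.0  # insert -> same insert (mean gap length 3)

    def __post_init__(self) -> None:
        if not np.isclose(self.match_emission.sum(), 1.0, atol=1e-9):
            raise ValueError("match emission must sum to 1")
        if not np.isclose(self.insert_emission.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emission must sum to 1")
        if not (0 < self.delta < 0.5 and 0 < self.epsilon < 1):
            raise ValueError("invalid transition probabilities")

    @property
    def transitions(self) -> np.ndarray:
        """Row-stochastic transition matrix over states (M, X, Y)."""
        d, e = self.delta, self.epsilon
        return np.array(
            [
                [1.0 - 2.0 * d, d, d],
                [1.0 - e, e, 0.0],
                [1.0 - e, 0.0, e],
            ]
        )

    @property
    def initial(self) -> np.ndarray:
        """Start distribution: same as the transitions out of match."""
        d = self.delta
        return np.array([1.0 - 2.0 * d, d, d])


# --------------------------------------------------------------------------
# pipeline thresholds
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrfWeights:
    """Alignment weights and reporting thresholds of the tandem-repeat scan
    (match/mismatch/indel scores, candidate match probabilities, minimum
    reported score, maximum period)."""

    match: int = 2
    mismatch: int = 7  # penalty magnitudes (applied as negative scores)
    indel: int = 7
    match_prob: int = 80
    indel_prob: int = 10
    min_score: int = 20
    max_period: int = 500


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of the calling pipeline in one place."""

    sv_min_span: int = 50
    bubble_align_cap: int = 10_000
    column_conf_threshold: float = 0.99
    mei_reciprocal_overlap: float = 0.80
    vntr_span_fraction: float = 0.50
    trf: TrfWeights = field(default_factory=TrfWeights)
    subtelomere_span: int = 5_000_000
    gc_filter: float = 0.60
    pattern_len_filter: int = 15
    # anchoring / alignment machinery
    min_anchor_length: int = 20
    consistency_rounds: int = 2
    sparse_cutoff: float = 1e-4
    full_dp_cap: int = 2_000  # alleles above this skip fine MSA (block layout)
    breakpoint_penalty: int | None = None  # default: 2 * min_anchor_length
    hmm: PairHmmParams = field(default_factory=PairHmmParams)

    def __post_init__(self) -> None:
        if self.sv_min_span <= 0 or self.bubble_align_cap <= 0:
            raise ValueError("thresholds must be positive")
        for frac in (
            self.column_conf_threshold,
            self.mei_reciprocal_overlap,
            self.vntr_span_fraction,
        ):
            if not 0.0 < frac <= 1.0:
                raise ValueError("fractions must be in (0, 1]")

    @property
    def effective_breakpoint_penalty(self) -> int:
        if self.breakpoint_penalty is not None:
            return self.breakpoint_penalty
        return 2 * self.min_anchor_length
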