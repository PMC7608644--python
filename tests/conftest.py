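"""Shared fixtures: the demo study run and a small, fast pipeline run.

Both are session-scoped because a full pipeline execution is the expensive
part of the suite; every test that needs end-to-end outputs shares them.
"""

from __future__ import annotations

import time

import pytest

from svscape.config import (
    ChromosomeSpec,
    GeneParams,
    PipelineConfig,
    SimulationConfig,
    demo_config,
)
from svscape.evaluate import match_truth
from svscape.pipeline import run_pipeline


@pytest.fixture(scope="session")
def pipe() -> PipelineConfig:
    return PipelineConfig()


def tiny_config(seed: int = 7) -> SimulationConfig:
    """A ~0.65 Mb, 27-variant study that runs end to end in under a minute."""
    return SimulationConfig(
        seed=seed,
        chromosomes=(
            ChromosomeSpec("chr1", 400_000, 180_000),
            ChromosomeSpec("chr2", 250_000, 90_000, acrocentric_p=True),
        ),
        subtelomere_span=30_000,
        n_vntr=12,
        n_mei=6,
        n_del=4,
        n_inv=3,
        n_subthreshold=2,
        subtelomeric_vntr_fold=3.0,
        gene=GeneParams(n_genes=40, length_range=(2_000, 12_000)),
    )


@pytest.fixture(scope="session")
def tiny_sim() -> SimulationConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_run(tiny_sim, tmp_path_factory):
    """(PipelineResult, output dir) for the small study, outputs written."""
    out = tmp_path_factory.mktemp("tiny_run")
    result = run_pipeline(tiny_sim, out_dir=out)
    return result, out


@pytest.fixture(scope="session")
def demo_run():
    """(PipelineResult, RecoveryReport, wall seconds) for the bundled demo
    study: five haplotypes over 5 Mb, 200 planted variants, seed 42."""
    t0 = time.time()
    result = run_pipeline(demo_config(seed=42))
    elapsed = time.time() - t0
    inversions = [c for calls in result.inversions.values() for c in calls]
    report = match_truth(result.truth, result.svs, inversions)
    return result, report, elapsed
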