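import pytest

from haplobin.pipeline import PipelineResult, run_pipeline
from haplobin.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The desk-scale study conditions: 2 x 1 Mb chromosomes, SNP every
    500 bp, 10% haplotype-specific regions, 200 gametes at 0.3x with 0.5%
    genotyping error, 10,000 ~15-kb reads."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_default(default_config) -> PipelineResult:
    """One full pipeline run under the default study conditions."""
    return run_pipeline(default_config)


@pytest.fixture(scope="session")
def pipeline_doublets() -> PipelineResult:
    """Pipeline run on a dataset with 10% doublets at 0.5x coverage.

    Four chromosomes: a doublet whose two components happened to inherit
    near-identical mosaics is intrinsically undetectable by any transition
    screen, and the chance of that collision shrinks rapidly with chromosome
    count (real karyotypes have many chromosomes)."""
    cfg = SimulationConfig(seed=7, n_chromosomes=4, n_gametes=150, coverage=0.5,
                           doublet_fraction=0.10, n_reads=100)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipelines_multi() -> list[PipelineResult]:
    """Three independent single-chromosome runs for seed-averaged checks."""
    out = []
    for seed in (11, 12, 13):
        cfg = SimulationConfig(seed=seed, n_chromosomes=1, n_reads=200)
        out.append(run_pipeline(cfg))
    return out
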