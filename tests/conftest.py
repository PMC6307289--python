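import pytest

from enhancekit.pipeline import PipelineConfig, run_pipeline
from enhancekit.simulate import SimulationConfig, simulate_all

SEED = 0


def small_sim_config(seed: int = SEED, **overrides) -> SimulationConfig:
    """A scaled-down simulation for fast unit tests (same structure as the
    full study conditions: 2 chromosomes, planted effects, SE loci)."""
    params = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=2_000_000,
        n_genes=60,
        n_peaks=400,
        n_se_loci=2,
        peaks_per_se_locus=5,
        n_artifact_peaks=4,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_all(small_sim_config())


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A full pipeline run on the small synthetic dataset; stitch window is
    scaled to the compressed genome's peak density (see docs/methods.md)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=SEED, simulation=small_sim_config(), stitch_dist=1500)
    return run_pipeline(cfg, outdir)
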