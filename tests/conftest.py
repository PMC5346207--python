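import numpy as np
import pytest

from scaffmap import simulate
from scaffmap.pipeline import PipelineConfig, run_synthetic_pipeline


def small_config() -> PipelineConfig:
    """Compact 3-chromosome study: fast enough for unit tests, large
    enough to carry every planted defect class."""
    cfg = PipelineConfig()
    cfg.genome.n_chromosomes = 3
    cfg.genome.length_range = (300_000, 400_000)
    cfg.fragmentation.n_scaffolds = 12
    cfg.fragmentation.n_chimeras = 1
    cfg.fragmentation.n_flipped = 2
    cfg.fragmentation.n_unplaced = 1
    cfg.fragmentation.n_gaps = 8
    cfg.maps.markers_per_chromosome = (30, 20)
    cfg.variants.n_snps = 10
    cfg.variants.n_indels = 8
    return cfg


@pytest.fixture(scope="session")
def small_truth():
    cfg = small_config()
    truth = simulate.simulate_truth_genome(cfg.genome, seed=11)
    scaffolds = simulate.fragment_into_scaffolds(truth, cfg.fragmentation, seed=12)
    markers = simulate.simulate_linkage_maps(truth, cfg.maps, seed=13)
    return truth, scaffolds, markers, cfg


@pytest.fixture(scope="session")
def small_pipeline():
    return run_synthetic_pipeline(small_config(), seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
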