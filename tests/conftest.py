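import numpy as np
import pytest
from hypothesis import settings

from teapop import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_matrix():
    """10 diploids x 300 sites on a 100-kb chromosome, 5% missing calls."""
    cfg = sd.SimConfig(n_samples=10, n_sites=300, chrom_length=100_000,
                       missing_rate=0.05, seed=42)
    return sd.simulate_neutral_population(cfg)


@pytest.fixture(scope="session")
def artifact_bundle():
    """2,000 clean SNPs stressed with labelled filtering artifacts."""
    cfg = sd.SimConfig(n_samples=20, n_sites=2000, chrom_length=500_000,
                       missing_rate=0.03, seed=11)
    matrix = sd.simulate_neutral_population(cfg)
    sites = list(sd.to_variant_sites(matrix))
    perturbed, labels = sd.inject_artifacts(sites,
                                            sd.ArtifactConfig(seed=12))
    return matrix, perturbed, labels


def label_survivor_positions(labels):
    """Positions failing no labelled criterion (the cascade oracle)."""
    fails = (labels.fails_hard | labels.fails_indel_proximity
             | labels.fails_quality | labels.fails_biallelic
             | labels.fails_depth | labels.fails_maf)
    return set(labels.pos[~fails])
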