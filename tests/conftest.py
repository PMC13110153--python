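import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tillmap.config import GenomeSpec, HnrtSpec, SegmentSpec, SimConfig
from tillmap.synthetic import build_toy_genome, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tiny_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A small, fast configuration for unit tests (2 chromosomes, 40 genes)."""
    kwargs = dict(
        seed=seed,
        n_dh_lines=8,
        n_f2=24,
        n_shared_artifacts=4,
        n_loci_per_chrom=30,
        genome_spec=GenomeSpec(
            chrom_lengths={"A1": 120_000, "C1": 120_000},
            genes_per_chrom={"A1": 40, "C1": 40},
            homoeologous_pairs=[("A1", "C1")],
        ),
        hnrt_spec=HnrtSpec(
            deletions=[
                SegmentSpec("D1", "A1", 4, 11, "deletion"),
                SegmentSpec("D2", "A1", 20, 27, "deletion"),
            ],
            duplication=SegmentSpec("P1", "C1", 10, 21, "duplication"),
        ),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return build_toy_genome(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale synthetic cohort (184 F2s, 4 chromosomes)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
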