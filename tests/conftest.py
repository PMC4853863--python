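import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pyrandom():
    return random.Random(12345)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small simulated cohort shared across tests (8 genomes, 6 markers)."""
    from markerrank.simulate import SimulationConfig, generate_dataset

    cfg = SimulationConfig(
        n_genomes=8,
        n_markers=6,
        n_background_genes=30,
        marker_length_nt=400,
        slow16s_length_nt=1100,
        protein_length_aa=60,
        tree_depth=0.8,
        n_lineages=2,
        lineage_sizes=(4, 4),
        cluster_size=2,
        seed=42,
    )
    out = tmp_path_factory.mktemp("tiny_cohort")
    truth = generate_dataset(cfg, out)
    return cfg, truth, out
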