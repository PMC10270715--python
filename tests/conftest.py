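import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from connsweep.atlas import load_atlas, load_subnetworks
from connsweep.synthetic import (
    SynthConfig,
    gen_connectomes,
    gen_participants,
    gen_template,
    participants_to_frame,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_atlas():
    return load_atlas("toy20")


@pytest.fixture(scope="session")
def toy_subnets(toy_atlas):
    return load_subnetworks(toy_atlas)


@pytest.fixture(scope="session")
def toy_template():
    return gen_template("toy20", 20, density=0.5, seed=7)


@pytest.fixture(scope="session")
def small_cohort(toy_template):
    """30-participant null cohort on the toy atlas (seeded, shared)."""
    config = SynthConfig(n_participants=30, seed=42, template=toy_template)
    participants = gen_participants(config)
    connectomes = gen_connectomes(participants, config)
    return config, participants, connectomes, participants_to_frame(participants)


def random_raw_counts(rng: np.random.Generator, n_nodes: int, scale: float = 20.0):
    """Random symmetric count + RD matrices for fixture construction."""
    iu = np.triu_indices(n_nodes, 1)
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    vals = rng.poisson(rng.uniform(0, scale, size=iu[0].size))
    vals[rng.random(iu[0].size) < 0.3] = 0
    counts[iu] = vals
    counts += counts.T
    rd = np.zeros((n_nodes, n_nodes))
    rdv = rng.uniform(4e-4, 9e-4, size=iu[0].size)
    rd[iu] = np.where(vals > 0, rdv, 0.0)
    rd += rd.T
    return counts, rd
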