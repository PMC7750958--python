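import numpy as np
import pytest

from idroute.simcore import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(**kw):
    """A reduced invasion scenario for fast property tests: two 200-kb
    chromosomes with 20-kb terminal clusters, N=200, 60 seed insertions."""
    base = dict(
        chromosome_lengths=[200_000, 200_000],
        cluster_lengths=20_000,
        recombination_cm_mb=4.0,
        N=200,
        n_fl_init=60,
        generations=150,
        u=0.1,
        c=0.0,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def stepping_runs():
    """Ten replicates of the ten-deme stepping-stone protocol (c=0.025,
    250 seed FL copies, migration of 100 individuals every 300 generations,
    sampled at generation 3000).  Shared by the route-information and
    private-ID acceptance checks."""
    from idroute.simcore import run_stepping_stone

    results = []
    for seed in range(1, 11):
        cfg = SimConfig(
            c=0.025, n_fl_init=250, n_populations=10, generations=3000,
            migration_interval=300, migration_size=100, record_every=100,
            seed=seed,
        )
        results.append(run_stepping_stone(cfg))
    return results
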