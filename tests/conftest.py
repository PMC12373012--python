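import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_genome():
    from methyl3c.genome import GenomeSpec

    return GenomeSpec.uniform(2, 200_000)


@pytest.fixture(scope="session")
def methylome_sim():
    """Four-type methylome simulation with planted DMRs, deep coverage."""
    from methyl3c import simulate as sim

    cfg = sim.SimulationConfig(
        seed=1,
        genome=sim.GenomeSpec.uniform(2, 400_000),
        n_cell_types=4,
        cells_per_type=10,
    )
    meth = dataclasses.replace(
        cfg.methylation, coverage_mean=20.0, n_ch_sites=0,
    )
    cfg = dataclasses.replace(cfg, methylation=meth)
    cfg = dataclasses.replace(
        cfg,
        methylation=dataclasses.replace(cfg.methylation, dmrs=sim.random_dmrs(cfg, n=20)),
    )
    cells, labels, truth = sim.simulate_methylomes(cfg)
    return cfg, cells, labels, truth
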