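import numpy as np
import pytest

from methcap import (
    SimulationConfig,
    make_target_panel,
    make_toy_genome,
    simulate_fragments,
)


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(11, length=50_000, n_islands=5, n_repeat_copies=8)


@pytest.fixture(scope="session")
def panel(toy_genome):
    return make_target_panel(toy_genome, 10, seed=12)


@pytest.fixture(scope="session")
def region_betas(panel):
    rng = np.random.default_rng(13)
    return {t.name: float(b) for t, b in zip(panel, rng.random(len(panel)))}


@pytest.fixture(scope="session")
def readset(toy_genome, panel, region_betas):
    cfg = SimulationConfig(
        seed=14,
        n_fragments=8_000,
        conversion_efficiency=1.0,
        region_betas=region_betas,
        on_target_fraction=0.8,
    )
    return simulate_fragments(toy_genome, panel, cfg)
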