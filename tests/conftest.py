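import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ttrnet.simulate import SimulationConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One fully generated dataset at the default study conditions."""
    return generate_dataset(SimulationConfig(rng_seed=3))


@pytest.fixture()
def toy_expression():
    """Tiny 4-transcript, 3+3+3 matrix with one strong planted ratio."""
    rng = np.random.default_rng(0)
    samples = [f"{g}_{i}" for g in ("LG", "HG", "HG_TTR") for i in (1, 2, 3)]
    design = pd.Series({s: s.rsplit("_", 1)[0] for s in samples})
    base = rng.uniform(20, 40, size=(4, 9))
    values = pd.DataFrame(base, index=[f"t{i}" for i in range(4)], columns=samples)
    return values, design


def two_block_config(seed: int) -> SimulationConfig:
    """The planted two-module design: 50 + 50 transcripts, no DE."""
    return SimulationConfig(
        n_coding=100,
        n_lncrna=0,
        n_de_up=0,
        n_de_down=0,
        n_trend_reversal=0,
        n_modules=2,
        module_size=50,
        n_cis_pairs=0,
        n_cerna_triads=0,
        rng_seed=seed,
    )


def trend_config(seed: int) -> SimulationConfig:
    """The trend-recovery study condition: 30 planted reversals, no modules."""
    return SimulationConfig(rng_seed=seed, n_modules=0)
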