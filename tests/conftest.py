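import numpy as np
import pytest

from auscult.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast synthetic cohort: 16 patients, 6-second clips."""
    cfg = SimulationConfig(n_per_class_centre=2, clip_seconds=6.0, seed=99)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_patients(tiny_cohort):
    _, cohort = tiny_cohort
    return [sp.record for sp in cohort]
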