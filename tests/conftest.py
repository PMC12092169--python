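import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """A 12x12 world with 20 bins (1320-2020 CE), both models, overlap."""
    from mtenm.synthetic import WorldConfig, generate_world

    cfg = WorldConfig(grid_nx=12, grid_ny=12, n_bins=20, seed=42)
    truth, biased, overlap = generate_world(cfg)
    return cfg, truth, biased, overlap


@pytest.fixture(scope="session")
def sampled_records(small_world):
    from mtenm.synthetic import TrueNiche, sample_occurrences

    cfg, truth, _, _ = small_world
    niche = TrueNiche()
    records = sample_occurrences(
        truth, niche, n_per_era={"fossil": 30, "historical": 50, "contemporary": 120}, seed=7
    )
    return niche, records
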