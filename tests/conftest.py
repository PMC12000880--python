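"""Shared fixtures.

Expensive simulations are session-scoped and reused across tests; seeds
are fixed so every run exercises identical study conditions.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import forkprof as fp
from forkprof.simulate import (
    default_mask_intervals,
    mask_from_intervals,
    sample_reads,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SIM_SEED = 3
READ_SEED = 103


@pytest.fixture(scope="session")
def small_layout():
    return fp.GenomeLayout(
        name="toy",
        length_bp=2_000,
        dif_pos=1,
        oric_pos=1_000,
        regions={"mid": (801, 1200)},
    )


@pytest.fixture(scope="session")
def default_config():
    return fp.default_scenario(seed=SIM_SEED, n_cells=8000)


@pytest.fixture(scope="session")
def default_sim(default_config):
    """Expected copy profiles + ground truth for the canonical scenario."""
    profiles, truth = fp.simulate_population(
        default_config, [0.0, 60.0, 120.0, 180.0]
    )
    return profiles, truth


@pytest.fixture(scope="session")
def default_reads(default_config, default_sim):
    """Poisson-sampled binned depth per timepoint, with the rrn-like mask."""
    profiles, _ = default_sim
    cfg = default_config
    mask = mask_from_intervals(
        default_mask_intervals(cfg), cfg.n_bins, cfg.bin_size
    )
    rng = np.random.default_rng(READ_SEED)
    return {
        t: sample_reads(
            profiles[t], cfg.mean_depth, rng, cfg.layout.length_bp,
            cfg.bin_size, mask,
        )
        for t in sorted(profiles)
    }


@pytest.fixture(scope="session")
def default_t0_features(default_config, default_reads):
    """Fitted t0 trendline and its feature calls for the canonical scenario."""
    res = fp.ReplicationProfile(default_reads[0.0], default_config.layout).fit()
    return res, res.call_features()
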