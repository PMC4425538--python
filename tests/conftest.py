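import numpy as np
import pytest

from ctqtl import EqtlEffectSpec, SimulationConfig, simulate_cohort


def small_config(seed=0, **overrides):
    """A fast 2-cohort configuration for unit tests."""
    defaults = dict(
        n_cohorts=2,
        samples_per_cohort=[120, 120],
        n_snps=30,
        n_probes=60,
        n_marker_probes=15,
        ld_block_size=3,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def training_fixture():
    """One cohort with measured cell counts, strong markers, one real eQTL."""
    config = SimulationConfig(
        n_cohorts=2,
        samples_per_cohort=[200, 200],
        n_snps=30,
        n_probes=80,
        n_marker_probes=20,
        marker_noise_sd=0.02,
        eqtl_effects=[
            EqtlEffectSpec(
                "rs000001", "probe_00080",
                beta_myeloid=0.8, beta_lymphoid=0.0,
                baseline_myeloid=1.0, baseline_lymphoid=0.5,
            )
        ],
        seed=11,
    )
    return config, simulate_cohort(config, 0), simulate_cohort(config, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
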