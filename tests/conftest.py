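"""Shared fixtures: small simulated experiments generated at test time."""

import numpy as np
import pytest

from emcap.simulate import PlantConfig, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def noiseless_sim():
    """Error-free, fully distinguishable simulation with perfect conversion."""
    cfg = SimConfig(
        seed=101,
        genome_length=300_000,
        n_targets=10,
        coverage=30,
        substitution_rate=0.0,
        insertion_rate=0.0,
        deletion_rate=0.0,
        conversion_efficiency=1.0,
        over_conversion_rate=0.0,
        duplicate_rate=0.0,
        distinguishable_only=True,
        n_somatic_snvs=0,
        snv_vaf=0.0,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-condition simulation at reduced genome size."""
    cfg = SimConfig(
        seed=202,
        genome_length=300_000,
        n_targets=10,
        coverage=30,
        n_somatic_snvs=20,
        snv_vaf=0.4,
        asm=PlantConfig(2, 20, 0.8),
    )
    return simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
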