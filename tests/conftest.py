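"""Shared fixtures: desk-scale simulated herds used across the suite."""

import numpy as np
import pytest

from crosskin import synth


@pytest.fixture(scope="session")
def clean_sim() -> synth.PopulationSim:
    """Noise-free desk-scale herd: genotypes observed exactly as simulated."""
    cfg = synth.SimulationConfig(
        n_sires=8, n_dams=10, n_f1=40, n_f2_backcross=20, n_f2_intercross=10,
        n_loci=500, frac_fixed_divergent=0.4, mean_depth=30.0,
        genotype_error_rate=0.0, missing_rate=0.0, seed=11,
    )
    return synth.simulate_population(cfg)


@pytest.fixture(scope="session")
def noisy_sim() -> synth.PopulationSim:
    """Herd with RAD-like noise: moderate depth, read errors, dropout."""
    cfg = synth.SimulationConfig(
        n_sires=8, n_dams=10, n_f1=40, n_f2_backcross=20, n_f2_intercross=10,
        n_loci=500, frac_fixed_divergent=0.4, mean_depth=15.0,
        genotype_error_rate=0.002, missing_rate=0.03, seed=12,
    )
    return synth.simulate_population(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
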