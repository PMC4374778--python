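import numpy as np
import pytest

from cnvquartet import (
    CallerProfile,
    CNVCall,
    SimulationConfig,
    Status,
    simulate_study,
    zero_noise_profile,
)

#: tiny genome for brute-force (per-base) oracles
TINY_GENOME = {"1": 100_000, "2": 60_000}


def call(chrom, start, end, status=Status.GAIN, **kw):
    return CNVCall(chrom=chrom, start=start, end=end, status=status, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20151)


@pytest.fixture(scope="session")
def noise_free_study():
    """Small study observed through error-free virtual callers: every
    downstream metric should attain its ideal value on this fixture."""
    cfg = SimulationConfig(
        n_families=4,
        n_cnvs_per_parent=25,
        population_cnv_pool_size=15,
        profiles=(zero_noise_profile("exact_a"), zero_noise_profile("exact_b")),
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """Small study with two imperfect virtual callers."""
    cfg = SimulationConfig(
        n_families=4,
        n_cnvs_per_parent=25,
        population_cnv_pool_size=15,
        profiles=(
            CallerProfile("sloppy", fp_rate=15, fn_prob=0.1, jitter_sd=300, frag_prob=0.2),
            CallerProfile("tight", fp_rate=3, fn_prob=0.03, jitter_sd=80),
        ),
        seed=12,
    )
    return simulate_study(cfg)
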