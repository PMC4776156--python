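import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """Miniature sequence-level dataset: 3 x 300 kb chromosomes, ~99 sites each."""
    from fourc.simulate import SimConfig, simulate_contact_profile, simulate_genome

    config = SimConfig(
        n_chromosomes=3,
        chromosome_length=300_000,
        inter_site_spacing=3_000,
        reads_per_replicate=20_000,
        error_rate=0.0,
        seed=42,
    )
    genome, library = simulate_genome(config)
    truth = simulate_contact_profile(library, config)
    return config, genome, library, truth


@pytest.fixture(scope="session")
def small_reads(small_sim):
    """One replicate of error-free reads over the miniature dataset."""
    from fourc.simulate import simulate_reads

    config, genome, library, truth = small_sim
    rng = np.random.default_rng(7)
    records, counts = simulate_reads(truth, genome, library, config, "rep1", rng)
    return records, counts
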