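import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from supergene import SceneSpec, SimulationSpec, build_scene, simulate_haplotypes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene():
    """Multi-contig scene with planted repeats and gene models."""
    return build_scene(SceneSpec(seed=11))


@pytest.fixture(scope="session")
def hemizygote():
    """Small diploid with the focal region on one of two haplotypes."""
    spec = SimulationSpec(
        genome_length=60_000,
        region_length=12_000,
        ploidy=2,
        copy_number=1,
        depth_per_haplotype=10.0,
        seed=7,
    )
    reference, truth = simulate_haplotypes(spec)
    return reference, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
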