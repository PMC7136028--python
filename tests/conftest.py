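import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amplimeth import simulate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def snp_amplicon():
    """Small diploid amplicon: 4 CpGs, the first being a C/A SNP-CpG."""
    return simulate.simulate_amplicon(
        length=80,
        cpg_offsets=[10, 30, 50, 70],
        gc_content=0.4,
        seed=11,
        name="toy_snp_amplicon",
        snp_offset=10,
        tss_offset=75,
    )


@pytest.fixture(scope="session")
def plain_amplicon():
    """Haploid amplicon with 9 CpGs, no SNP."""
    return simulate.simulate_amplicon(
        length=100,
        cpg_offsets=[5, 15, 25, 35, 45, 55, 65, 75, 85],
        gc_content=0.4,
        seed=7,
        name="toy_amplicon",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
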