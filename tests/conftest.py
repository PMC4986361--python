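import numpy as np
import pytest

from summitshift.formats_io import PWM, GenomicInterval, Summit
from summitshift.simulate import SyntheticConfig, generate


def make_summit(chrom, pos, sample="s1", protein="CTCF", height=0.0):
    return Summit(
        interval=GenomicInterval(chrom, pos, pos + 1),
        sample_id=sample,
        protein=protein,
        height=height,
    )


@pytest.fixture
def uniform_pwm():
    return PWM(matrix=np.full((4, 4), 0.25))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Small noiseless dataset: pipeline output must equal configured truth."""
    return generate(SyntheticConfig(n_sites=120, chrom_length=120 * 300,
                                    summit_noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions at reduced site count for unit tests."""
    return generate(SyntheticConfig(n_sites=200, chrom_length=200 * 300,
                                    summit_noise_sd=10.0, seed=5))
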