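import numpy as np
import pytest

from hhmismatch import PhantomSpec, generate_phantom, segment_study


@pytest.fixture(scope="session")
def noise_free_spec():
    return PhantomSpec(hu_noise_sd=0.0, perfusion_noise_frac=0.0,
                       onset_to_ct_h=1.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    """Study + ground truth of a deterministic noise-free phantom (onset 1 h)."""
    return generate_phantom(noise_free_spec, seed=7)


@pytest.fixture(scope="session")
def noise_free_masks(noise_free_phantom):
    study, _ = noise_free_phantom
    return segment_study(study)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
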