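import numpy as np
import pytest

from axonwrap import synthetic as syn


@pytest.fixture(scope="session")
def clean_field():
    """Noise- and blur-free 3x3 field: one fully wrapped pillar, 10 nuclei."""
    spec = syn.SyntheticFieldSpec(
        wrap_events=(syn.WrapEvent(4, 0, 3, 1.0, 0.0),),
        n_nuclei=10,
        blur_sigma_um=0.0,
        gaussian_sd=0.0,
        poisson=False,
        seed=7,
    )
    stack, truth = syn.generate_field(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_field():
    """Default-noise randomized field with ground truth."""
    spec = syn.random_field_spec(11, noise=True)
    stack, truth = syn.generate_field(spec)
    return spec, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
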