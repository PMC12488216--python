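import numpy as np
import pytest

import ewaldhand as eh


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A 32^3 phantom that fits its box, for fast unit tests."""
    return eh.PhantomSpec(box=32, pixel_size=3.0, chirality="right-helix")


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """Noise-free 300-particle dataset at exaggerated curvature."""
    return eh.make_dataset(small_spec, 300, noise_sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def small_recon(small_dataset):
    ds = small_dataset
    return eh.reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)


@pytest.fixture(scope="session")
def small_maps(small_recon):
    return (
        eh.finalize_volume(small_recon.acc_real),
        eh.finalize_volume(small_recon.acc_imag),
    )
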