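import numpy as np
import pytest

from perfmap.phantom import PhantomConfig, generate_phantom
from perfmap.pipeline import RunConfig, compute_priors
from perfmap.volume_io import Geometry, Mask, Volume


@pytest.fixture(scope="session")
def default_case():
    """Default 5-vessel phantom (one full helix turn in the muscle), seed 1."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_case():
    return generate_phantom(PhantomConfig(seed=2, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_priors(default_case):
    """(AnatomyPriors, enhanced volume) for the default phantom."""
    cfg = RunConfig(phantom=True)
    case = default_case
    return compute_priors(
        case.image, case.muscle_mask_left, case.muscle_mask_right, cfg
    )


@pytest.fixture(scope="session")
def noise_free_priors(noise_free_case):
    cfg = RunConfig(phantom=True)
    case = noise_free_case
    return compute_priors(
        case.image, case.muscle_mask_left, case.muscle_mask_right, cfg
    )


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=np.uint8)
    return Mask(geometry=Geometry(shape=arr.shape, spacing=spacing), values=arr)


def make_volume(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=float)
    return Volume(geometry=Geometry(shape=arr.shape, spacing=spacing), values=arr)
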