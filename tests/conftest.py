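import numpy as np
import pytest

from neolesion.phantom import PhantomConfig, generate_case
from neolesion.volio import BinaryMask, LongitudinalCase, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom() -> LongitudinalCase:
    """A deterministic 48^3 phantom with 2 new and 2 stable lesions."""
    cfg = PhantomConfig(shape=(48, 48, 48), n_stable_lesions=2,
                        n_new_lesions=2, lesion_radius_range=(2, 4), seed=7)
    return generate_case(cfg)


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> Volume:
    data = np.asarray(data, dtype=np.float32)
    affine = np.diag(list(spacing) + [1.0])
    return Volume(data, spacing, affine)


def make_mask(data, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    data = np.asarray(data)
    affine = np.diag(list(spacing) + [1.0])
    return BinaryMask(data, spacing, affine)
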