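import numpy as np
import pytest

from alffpipe.synthetic import (
    GroupEffectSpec,
    PhantomSpec,
    make_phantom_masks,
    make_regions,
)
from alffpipe.types import BoldSeries


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def default_masks(default_spec):
    return make_phantom_masks(default_spec)


@pytest.fixture(scope="session")
def default_regions(default_spec, default_masks):
    return make_regions(default_masks[1], default_spec.region_sizes, seed=default_spec.seed)


@pytest.fixture(scope="session")
def quiet_spec() -> PhantomSpec:
    """Noiseless, driftless, bin-aligned phantom for exact spectral checks."""
    return PhantomSpec(
        noise_sd=0.0,
        drift_slope=0.0,
        ar_coefficient=0.0,
        confound_sd=0.0,
        amplitude_jitter_sd=0.0,
        n_oscillators=1,
        bin_aligned=True,
        seed=0,
    )


@pytest.fixture
def ctl_effect() -> GroupEffectSpec:
    return GroupEffectSpec(group="CTL", n_subjects=4)


def make_series(data: np.ndarray, tr: float = 2.0) -> BoldSeries:
    return BoldSeries(data=np.asarray(data, dtype=float), tr=tr, voxel_size=(3.0, 3.0, 3.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
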