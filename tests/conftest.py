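import numpy as np
import pytest

from alffkit.synth import EffectROI, SynthConfig
from alffkit.types import BandSpec, BrainMask, Fmri4D, ScalarMap


@pytest.fixture
def eye_affine():
    return np.eye(4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def band():
    return BandSpec(0.01, 0.08)


@pytest.fixture
def tiny_run(rng, eye_affine):
    """A small random 4D run: 4x4x4 grid, 64 timepoints, TR 2 s."""
    data = rng.normal(size=(4, 4, 4, 64))
    return Fmri4D(data, tr_s=2.0, affine=eye_affine, subject_id="sub-01")


@pytest.fixture
def full_mask(eye_affine):
    return BrainMask(np.ones((4, 4, 4), dtype=bool), eye_affine)


def random_maps(rng, n, shape=(4, 4, 4), affine=None, kind="malff"):
    affine = np.eye(4) if affine is None else affine
    return [ScalarMap(rng.normal(size=shape) + 5.0, affine, kind=kind)
            for _ in range(n)]


@pytest.fixture
def small_cohort_config():
    """Cheap cohort for integration tests: 8^3 grid, 32 volumes."""
    return SynthConfig(
        grid_dims=(8, 8, 8),
        voxel_size_mm=(3.0, 3.0, 3.0),
        tr_s=2.0,
        n_volumes=32,
        n_per_group=4,
        baseline_amp=1.0,
        effect_rois=(EffectROI((4, 4, 4), 5.0, 2.0),),
        white_noise_sd=0.3,
        n_sinusoids=2,
        seed=7,
    )
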