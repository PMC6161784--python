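import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pethet.imgio import PETVolume, VOIMask

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_lesion(values_3d, spacing=(1.0, 1.0, 1.0), pad=1, background=0.0,
                site="bone", patient_id="P000", lesion_id="L0"):
    """Embed a dense block of lesion values in a padded background grid."""
    values_3d = np.asarray(values_3d, dtype=float)
    shape = tuple(s + 2 * pad for s in values_3d.shape)
    grid = np.full(shape, float(background))
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(pad, pad + s) for s in values_3d.shape)
    grid[sl] = values_3d
    mask[sl] = True
    vol = PETVolume(values=grid, spacing_mm=spacing)
    voi = VOIMask(mask=mask, patient_id=patient_id, site=site, lesion_id=lesion_id)
    return vol, voi


def checkerboard(shape):
    """3D parity checkerboard of values {0, 1}."""
    idx = np.indices(shape).sum(axis=0)
    return (idx % 2).astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def constant_lesion():
    return make_lesion(np.full((3, 3, 3), 5.0))


@pytest.fixture
def checkerboard_lesion():
    return make_lesion(checkerboard((4, 4, 4)))
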