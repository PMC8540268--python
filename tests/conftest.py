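import numpy as np
import pytest

from peritex import GridGeometry, PhantomSpec


@pytest.fixture
def iso_geom():
    """Small isotropic 1 mm grid for hand-checkable geometry tests."""
    return GridGeometry((9, 9, 9), (1.0, 1.0, 1.0))


@pytest.fixture
def small_phantom_spec():
    """Compact phantom used wherever full-size volumes are unnecessary."""
    return PhantomSpec(
        grid_shape=(32, 32, 20),
        spacing_mm=(3.0, 3.0, 3.0),
        tumor_center_mm=(30.0, 46.5, 28.5),
        tumor_radii_mm=(7.0, 7.0, 7.0),
        rng_seed=11,
    )


def random_roi(rng, shape=(5, 5, 5), n_levels=4, p_mask=0.6):
    """Random level grid + mask fixture shared by oracle-equivalence tests."""
    mask = rng.random(shape) < p_mask
    if mask.sum() < 3:
        mask[tuple(rng.integers(0, s) for s in shape)] = True
        mask[0, 0, 0] = mask[-1, -1, -1] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, int(mask.sum()))
    return levels, mask
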