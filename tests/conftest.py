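import numpy as np
import pytest

from nodal_petrad.images import ROIMask, SUVImage


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom shared by read-only tests."""
    from nodal_petrad.synthetic import PhantomSpec, simulate_patient_images
    return simulate_patient_images(PhantomSpec(n_nodes=3, seed=7))


def make_roi(values, spacing=(1.0, 1.0, 1.0), mask=None):
    """Wrap a 3D array (or nested list) as (SUVImage, ROIMask)."""
    arr = np.asarray(values, dtype=float)
    image = SUVImage(arr, spacing)
    ind = np.ones(arr.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    return image, ROIMask(ind, spacing=spacing)


@pytest.fixture
def line_roi():
    """Four voxels along x holding [0.2, 0.6, 1.0, 2.3], rest masked out."""
    arr = np.zeros((4, 3, 3))
    arr[:, 1, 1] = [0.2, 0.6, 1.0, 2.3]
    mask = np.zeros_like(arr, dtype=bool)
    mask[:, 1, 1] = True
    return make_roi(arr, mask=mask)
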