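import numpy as np
import pytest

from rcfat.geometry import LabelMask, VolumeGeometry
from rcfat.phantom import default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def uniform_phantom():
    """Noise-free three-muscle phantom with uniform per-muscle fat fractions."""
    spec = default_phantom_spec(noise_sd=0.0, seed=1)
    vol, mask, truth = make_phantom(spec)
    return vol, mask, truth


@pytest.fixture
def small_geometry():
    return VolumeGeometry(in_plane_spacing=(1.2, 1.2), slice_thickness=2.0, n_slices=4)


def random_blob_mask(rng, shape=(12, 32, 32), label=1):
    """Random single-muscle mask: a lumpy ellipsoid across a random slice range."""
    n_slices = shape[0]
    lo = int(rng.integers(0, 3))
    hi = int(rng.integers(n_slices - 4, n_slices))
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[1], 0 : shape[2]]
    cr = rng.uniform(shape[1] * 0.3, shape[1] * 0.7)
    cm = rng.uniform(shape[2] * 0.3, shape[2] * 0.7)
    for s in range(lo, hi + 1):
        ar = rng.uniform(4, shape[1] / 2 - 2)
        ac = rng.uniform(4, shape[2] / 2 - 2)
        labels[s][((rr - cr) / ar) ** 2 + ((cc - cm) / ac) ** 2 <= 1.0] = label
    geom = VolumeGeometry(
        in_plane_spacing=(1.2, 1.2), slice_thickness=2.0, n_slices=n_slices
    )
    return LabelMask(labels=labels, label_names={label: "M"}, geometry=geom)
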