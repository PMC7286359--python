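import numpy as np
import pytest

from vulquant.imaging import ImageStack, Projection
from vulquant.synthgen import ACStackParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def noiseless_params():
    """AC stack parameters with every stochastic element disabled."""
    def make(**overrides):
        base = dict(
            rho_dv=1.0, rho_ap=1.0, n_punctae=0, background=0.0,
            gaussian_noise_sd=0.0, poisson_noise=False, seed=0,
        )
        base.update(overrides)
        return ACStackParams(**base)
    return make


@pytest.fixture
def small_stack(rng):
    """A random 16-bit stack with unit calibration."""
    data = rng.integers(0, 2**16, size=(6, 20, 24), dtype=np.uint16)
    return ImageStack(data, (0.2, 0.1, 0.1), "test")


def naive_half_ratio(pixels, mask, split_centroid, axis):
    """Two-loop pixel-sum oracle for the polarity index.

    Independent of the vectorised implementation: walks every pixel,
    accumulates sums and counts per half, excludes on-line pixels.
    """
    cy, cx = split_centroid
    pos_sum = pos_n = neg_sum = neg_n = 0.0
    for y in range(pixels.shape[0]):
        for x in range(pixels.shape[1]):
            if not mask[y, x]:
                continue
            coord, c = (y, cy) if axis == "DV" else (x, cx)
            if coord > c:
                pos_sum += pixels[y, x]
                pos_n += 1
            elif coord < c:
                neg_sum += pixels[y, x]
                neg_n += 1
    return (pos_sum / pos_n) / (neg_sum / neg_n)


@pytest.fixture
def half_ratio_oracle():
    return naive_half_ratio


@pytest.fixture
def uniform_projection():
    def make(value=1.0, shape=(16, 16)):
        return Projection(np.full(shape, float(value)))
    return make
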