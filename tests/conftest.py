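import numpy as np
import pytest

from lifespan_localfc import MotionTrace, VolumeSeries


def make_series(
    data: np.ndarray, tr: float = 1.97, mask: np.ndarray | None = None,
    voxel_mm: float = 3.0,
) -> VolumeSeries:
    """Wrap a raw 4D array as a VolumeSeries with a simple scaled affine."""
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return VolumeSeries(data=data, affine=affine, tr=tr, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_series(rng):
    """A small random 4D series with broadly distributed correlations:
    three latent signals with random non-negative loadings plus noise."""

    def _make(shape=(8, 8, 8), t=60, seed=None, tr=1.97):
        r = np.random.default_rng(seed) if seed is not None else rng
        latents = r.standard_normal((3, t))
        loadings = r.uniform(0, 1, size=(*shape, 3))
        data = np.einsum("...l,lt->...t", loadings, latents)
        data += 0.8 * r.standard_normal((*shape, t))
        return make_series(data, tr=tr)

    return _make


@pytest.fixture
def zero_motion():
    def _make(t):
        return MotionTrace(np.zeros((t, 6)))

    return _make
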