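import numpy as np
import pytest

from donkey.kde import BandwidthModel, KDEModel, PointSet


def make_kde(points, cov, scales=None, alpha=1.0, normalize=False):
    """KDE model with an explicitly chosen covariance (bypasses fitting)."""
    ps = PointSet(np.asarray(points, dtype=float), normalize=normalize)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    scales = np.ones(ps.n_points) if scales is None else np.asarray(scales)
    bw = BandwidthModel(
        pilot_covariance=cov,
        local_scales=scales,
        alpha=alpha,
        abramson_enabled=False,
    )
    return KDEModel(ps, bw)


@pytest.fixture
def model_01():
    """Two points at 0 and 1 with unit kernels: a unimodal 1-D density."""
    return make_kde([[0.0], [1.0]], [[1.0]])


@pytest.fixture
def model_01_narrow():
    """Two points at 0 and 1 with tight kernels: a bimodal 1-D density."""
    return make_kde([[0.0], [1.0]], [[0.01]])


@pytest.fixture
def two_clouds():
    """Two tight, well-separated 2-D Gaussian clouds with labels."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0], 0.05, size=(30, 2))
    b = rng.normal([1.0, 0.0], 0.05, size=(30, 2))
    pts = np.vstack([a, b])
    labels = np.array([0] * 30 + [1] * 30)
    return pts, labels


def grid_modes_1d(model, lo, hi, n=4001):
    """Dense-grid mode locations of a 1-D KDE (independent oracle)."""
    xs = np.linspace(lo, hi, n)
    dens = model.density_many(xs[:, None])
    modes = [
        xs[i]
        for i in range(1, n - 1)
        if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]
    ]
    return np.array(modes)
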