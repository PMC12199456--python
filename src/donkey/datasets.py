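"""Seeded generators for the synthetic clustering benchmarks.

The 2-D toy sets (anisotropic blobs, variance-varied blobs, concentric
circles) follow the standard configurations used throughout the clustering
literature to probe anisotropy, density contrast and concave shapes.  The
multidimensional benchmark places isotropic Gaussian clusters at the
vertices of a regular unit simplex, so the cluster separation is exactly
one in every dimension and only the standard deviation controls overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticDataset",
    "make_blobs_aniso",
    "make_varied",
    "make_circles",
    "make_simplex",
    "simplex_vertices",
]

# conventional three-blob center layout (shared by the anisotropic and
# varied sets); two of the sheared centers end up close together, which is
# the intended challenge of the anisotropic set
BLOB_CENTERS = np.array(
    [
        [-8.94709165, -5.46276435],
        [-4.58938989, 0.08876178],
        [1.93875432, 0.50513613],
    ]
)
#: common shear applied to the anisotropic blobs (misaligns principal axes)
ANISO_TRANSFORM = np.array([[0.6, -0.6], [-0.4, 0.8]])
#: per-cluster standard deviations of the variance-varied set
VARIED_STDS = (1.0, 2.5, 0.5)


@dataclass
class SyntheticDataset:
    """Points with ground-truth labels and full generation provenance."""

    points: np.ndarray
    truth_labels: np.ndarray
    generator_name: str
    parameters: dict
    seed: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _split_counts(n_total: int, k: int) -> np.ndarray:
    """Split ``n_total`` into ``k`` parts as evenly as possible."""
    base, extra = divmod(n_total, k)
    return np.array([base + (i < extra) for i in range(k)])


def make_blobs_aniso(n_total: int = 500, seed: int = 0) -> SyntheticDataset:
    """Three same-covariance Gaussian clusters under a common shear.

    Isotropic unit-variance clusters are sampled at the conventional
    centers and the whole set is sheared by one linear transform, giving
    three highly anisotropic clusters whose principal axes are not aligned
    with the feature axes, two of them close-lying.
    """
    rng = np.random.default_rng(seed)
    counts = _split_counts(n_total, 3)
    points, labels = [], []
    for k, cnt in enumerate(counts):
        points.append(rng.normal(BLOB_CENTERS[k], 1.0, size=(cnt, 2)))
        labels.append(np.full(cnt, k))
    x = np.vstack(points) @ ANISO_TRANSFORM
    return SyntheticDataset(
        points=x,
        truth_labels=np.concatenate(labels),
        generator_name="blobs_aniso",
        parameters={"n_total": n_total},
        seed=seed,
    )


def make_varied(n_total: int = 500, seed: int = 0) -> SyntheticDataset:
    """Three isotropic Gaussian clusters of different variances, overlapping.

    Standard deviations 1.0, 2.5 and 0.5 at the conventional centers; the
    wide middle cluster overlaps both neighbours, testing the handling of
    density contrast at shared boundaries.
    """
    rng = np.random.default_rng(seed)
    counts = _split_counts(n_total, 3)
    points, labels = [], []
    for k, cnt in enumerate(counts):
        points.append(rng.normal(BLOB_CENTERS[k], VARIED_STDS[k], size=(cnt, 2)))
        labels.append(np.full(cnt, k))
    return SyntheticDataset(
        points=np.vstack(points),
        truth_labels=np.concatenate(labels),
        generator_name="varied",
        parameters={"n_total": n_total, "stds": list(VARIED_STDS)},
        seed=seed,
    )


def make_circles(
    n_total: int = 500,
    noise_sd: float = 0.03,
    radius_ratio: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Two separated concentric rings (concave clusters).

    Points are placed uniformly by angle (evenly spaced, with a random
    phase per ring) on circles of radius 1 and ``radius_ratio``, then
    perturbed radially by Gaussian noise of standard deviation
    ``noise_sd``.  Even angular spacing is the conventional construction
    for this benchmark; the ring density is then uniform up to the radial
    noise.
    """
    if not 0.0 < radius_ratio < 1.0:
        raise ValueError("radius_ratio must lie in (0, 1)")
    gap = 1.0 - radius_ratio
    if noise_sd * 6.0 > gap:
        warnings.warn(
            "radial noise is large enough that the rings may touch",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    counts = _split_counts(n_total, 2)
    points, labels = [], []
    for k, (radius, cnt) in enumerate(zip((1.0, radius_ratio), counts)):
        theta = np.linspace(0.0, 2.0 * np.pi, cnt, endpoint=False)
        theta = theta + rng.uniform(0.0, 2.0 * np.pi)
        r = radius + rng.normal(0.0, noise_sd, cnt) if noise_sd > 0 else radius
        points.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        labels.append(np.full(cnt, k))
    return SyntheticDataset(
        points=np.vstack(points),
        truth_labels=np.concatenate(labels),
        generator_name="circles",
        parameters={
            "n_total": n_total,
            "noise_sd": noise_sd,
            "radius_ratio": radius_ratio,
        },
        seed=seed,
    )


def simplex_vertices(dim: int) -> np.ndarray:
    """Vertices of a regular ``dim``-simplex with unit edge length.

    Uses the standard recursive construction: each new vertex sits above
    the centroid of the previous ones at the height that makes every
    pairwise distance exactly one.  Any congruent embedding is equivalent
    downstream because the clustering is invariant to rotation and
    translation after feature normalization.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    v = np.zeros((dim + 1, dim))
    for i in range(1, dim + 1):
        # place vertex i equidistant from vertices 0..i-1
        centroid = v[:i, : i - 1].mean(axis=0) if i > 1 else np.zeros(0)
        v[i, : i - 1] = centroid
        # height chosen so |v_i - v_0| = 1
        sq = 1.0 - np.sum((v[i, : i - 1] - v[0, : i - 1]) ** 2)
        v[i, i - 1] = np.sqrt(sq)
    return v


#: edge length of the standard unit simplex (vertices at unit basis vectors)
SIMPLEX_EDGE = float(np.sqrt(2.0))


def make_simplex(
    dim: int,
    sigma: float = 0.1,
    per_cluster: int = 100,
    seed: int = 0,
    edge: float = SIMPLEX_EDGE,
) -> SyntheticDataset:
    """Isotropic Gaussian clusters at the vertices of a regular unit simplex.

    ``dim + 1`` clusters of ``per_cluster`` points each at the vertices of
    the standard unit ``dim``-simplex (the one spanned by the unit basis
    vectors, embedded in ``dim`` dimensions), whose edge length is sqrt(2);
    pass ``edge`` to rescale.  ``sigma`` controls the overlap (0.1 none,
    0.2 small, 0.3 large).
    """
    verts = simplex_vertices(dim) * edge
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for k, vert in enumerate(verts):
        points.append(rng.normal(vert, sigma, size=(per_cluster, dim)))
        labels.append(np.full(per_cluster, k))
    return SyntheticDataset(
        points=np.vstack(points),
        truth_labels=np.concatenate(labels),
        generator_name="simplex",
        parameters={
            "dim": dim,
            "sigma": sigma,
            "per_cluster": per_cluster,
            "edge": edge,
        },
        seed=seed,
    )
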