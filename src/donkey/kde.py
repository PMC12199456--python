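"""Adaptive Gaussian kernel density estimation.

The density model underlying the clustering is a Gaussian KDE whose single
pilot covariance ``C`` is chosen by maximizing the leave-one-out likelihood
of the data, and whose per-point covariances ``C_k = lambda_k * C`` are then
obtained by Abramson's local rescaling: kernels broaden in sparse regions
and narrow in dense ones, with the geometric mean of the factors pinned to
one.  Everything downstream (mode seeking, saddle-point merging) consumes
the analytic density, gradient and Hessian exposed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .exceptions import InsufficientDataError, InvalidBandwidthError

logger = logging.getLogger(__name__)

__all__ = [
    "PointSet",
    "BandwidthModel",
    "KDEModel",
    "gaussian_kernel",
    "loo_log_likelihood",
    "optimize_covariance",
    "abramson_rescale",
]

#: ridge added to the covariance each fixed-point iteration (degenerate data)
RIDGE = 1e-10
#: eigenvalue floor below which a covariance is treated as numerically singular
EIG_FLOOR = 1e-12


class PointSet:
    """An ``N x D`` data matrix with per-feature [0, 1] normalization.

    Parameters
    ----------
    points : array_like, shape (N, D)
        Raw data, one row per point.
    normalize : bool
        Rescale each feature affinely to the range [0, 1].  Constant
        (zero-range) columns carry no information and are dropped with a
        log message; their indices are recorded in ``dropped_columns``.

    The affine map is retained (``feature_min``, ``feature_max``) so that
    locations found in normalized coordinates can be mapped back to the
    original units.
    """

    def __init__(self, points, normalize: bool = True):
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2:
            raise ValueError("points must be a 2-D array (N rows, D features)")
        if pts.shape[0] < 2:
            raise InsufficientDataError(
                "at least two data points are required (leave-one-out)"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite values")

        self.raw = pts
        col_min = pts.min(axis=0)
        col_max = pts.max(axis=0)
        degenerate = np.isclose(col_max - col_min, 0.0)
        self.dropped_columns = np.flatnonzero(degenerate)
        self.kept_columns = np.flatnonzero(~degenerate)
        if self.kept_columns.size == 0:
            raise InsufficientDataError("all feature columns are constant")
        if self.dropped_columns.size:
            logger.info(
                "dropping %d constant feature column(s): %s",
                self.dropped_columns.size,
                self.dropped_columns.tolist(),
            )
        pts = pts[:, self.kept_columns]
        self.normalized = bool(normalize)
        if normalize:
            self.feature_min = col_min[self.kept_columns]
            self.feature_max = col_max[self.kept_columns]
            self.points = (pts - self.feature_min) / (
                self.feature_max - self.feature_min
            )
        else:
            self.feature_min = np.zeros(pts.shape[1])
            self.feature_max = np.ones(pts.shape[1])
            self.points = pts.copy()

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates from normalized space back to the original units."""
        x = np.asarray(x, dtype=float)
        return x * (self.feature_max - self.feature_min) + self.feature_min

    def to_dict(self) -> dict:
        return {
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "normalized": self.normalized,
        }


@dataclass
class BandwidthModel:
    """Pilot covariance plus per-point Abramson rescaling factors.

    ``local_scales`` holds the scalar factors ``lambda_k`` such that point
    ``k`` uses covariance ``lambda_k * C``; they are all one until the
    Abramson step runs.  ``alpha`` is the global broadening parameter: the
    kernel covariance actually used is ``alpha * lambda_k * C``.
    """

    pilot_covariance: np.ndarray
    local_scales: np.ndarray
    geometric_mean_density: float = np.nan
    alpha: float = 1.0
    abramson_enabled: bool = True
    iterations_used: int = 0
    converged: bool = True
    loo_history: list = field(default_factory=list)

    def __post_init__(self):
        self.pilot_covariance = np.asarray(self.pilot_covariance, dtype=float)
        self.local_scales = np.asarray(self.local_scales, dtype=float)
        _check_spd(self.pilot_covariance)
        if np.any(self.local_scales <= 0):
            raise InvalidBandwidthError("local scales must be positive")

    def to_dict(self) -> dict:
        return {
            "pilot_covariance": self.pilot_covariance.tolist(),
            "local_scales": self.local_scales.tolist(),
            "geometric_mean_density": float(self.geometric_mean_density),
            "alpha": float(self.alpha),
            "abramson_enabled": bool(self.abramson_enabled),
            "iterations_used": int(self.iterations_used),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandwidthModel":
        return cls(
            pilot_covariance=np.array(d["pilot_covariance"]),
            local_scales=np.array(d["local_scales"]),
            geometric_mean_density=d.get("geometric_mean_density", np.nan),
            alpha=d.get("alpha", 1.0),
            abramson_enabled=d.get("abramson_enabled", True),
            iterations_used=d.get("iterations_used", 0),
            converged=d.get("converged", True),
        )


def _check_spd(cov: np.ndarray) -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise InvalidBandwidthError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise InvalidBandwidthError("covariance must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise InvalidBandwidthError(
            "covariance is not positive definite"
        ) from exc


def gaussian_kernel(displacement, covariance, alpha: float = 1.0) -> float:
    """Normalized Gaussian kernel value at ``displacement``.

    With broadening ``alpha`` the kernel is the Gaussian with covariance
    ``alpha * C``, i.e. ``det(2 pi alpha C)^{-1/2} exp(-x^T C^{-1} x /
    (2 alpha))``, which integrates to one for any ``alpha > 0`` and reduces
    to the plain Gaussian kernel at ``alpha = 1``.
    """
    if alpha <= 0:
        raise InvalidBandwidthError("alpha must be positive")
    d = np.atleast_1d(np.asarray(displacement, dtype=float))
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape[0] != d.shape[0]:
        raise ValueError(
            f"dimension mismatch: displacement has length {d.shape[0]}, "
            f"covariance is {cov.shape[0]}x{cov.shape[1]}"
        )
    _check_spd(cov)
    dim = d.shape[0]
    c, low = cho_factor(cov)
    quad = float(d @ cho_solve((c, low), d))
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    log_norm = -0.5 * (dim * np.log(2.0 * np.pi * alpha) + logdet)
    return float(np.exp(log_norm - 0.5 * quad / alpha))


def _pairwise_quad(points: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Quadratic forms (Y_i - Y_j)^T C^{-1} (Y_i - Y_j) for all pairs."""
    c, low = cho_factor(cov)
    # whiten: q_ij = |W(Y_i - Y_j)|^2 with W^T W = C^{-1}
    white = cho_solve((c, low), points.T).T  # C^{-1} Y
    # q_ij = (Y_i-Y_j) . (C^{-1}Y_i - C^{-1}Y_j)
    cross = points @ white.T
    diag = np.einsum("nd,nd->n", points, white)
    return diag[:, None] + diag[None, :] - cross - cross.T


def loo_log_likelihood(point_set: PointSet, covariance) -> float:
    """Mean log leave-one-out density of the data under a uniform covariance.

    Returns ``(1/N) sum_i log[(1/(N-1)) sum_{j != i} K(Y_i - Y_j | C)]``.
    Excluding the self term keeps the maximizer away from the degenerate
    zero-bandwidth solution.
    """
    pts = point_set.points
    n, dim = pts.shape
    if n < 2:
        raise InsufficientDataError("leave-one-out requires N >= 2")
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    _check_spd(cov)
    q = _pairwise_quad(pts, cov)
    sign, logdet = np.linalg.slogdet(cov)
    log_norm = -0.5 * (dim * np.log(2.0 * np.pi) + logdet)
    logk = log_norm - 0.5 * q
    np.fill_diagonal(logk, -np.inf)
    per_point = logsumexp(logk, axis=1) - np.log(n - 1)
    return float(per_point.mean())


def optimize_covariance(
    point_set: PointSet, tol: float = 1e-6, max_iter: int = 500
) -> BandwidthModel:
    """Fixed-point iteration for the leave-one-out-optimal pilot covariance.

    Starting from the identity (an overestimate on [0,1]-normalized data, so
    the fixed point is approached from above), each sweep replaces ``C`` by
    the average over points ``i`` of the kernel-weighted covariance of the
    differences ``Y_i - Y_j``:

        C <- (1/N) sum_i [ sum_{j!=i} w_ij d_ij d_ij^T / sum_{j!=i} w_ij ]

    with ``w_ij = K(d_ij | C)``.  Convergence is declared when the relative
    Frobenius change drops below ``tol``.  A tiny ridge keeps the iteration
    alive on data that is degenerate in some direction.
    """
    pts = point_set.points
    n, dim = pts.shape
    if n < 2:
        raise InsufficientDataError("covariance optimization requires N >= 2")
    diffs = pts[:, None, :] - pts[None, :, :]  # (N, N, D)
    if np.allclose(diffs, 0.0):
        raise InsufficientDataError("all points identical; covariance undefined")
    cov = np.eye(dim)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = _pairwise_quad(pts, cov)
        np.fill_diagonal(q, np.inf)
        # kernel normalization is shared by every pair and cancels in the
        # per-row ratio; stabilize the exponentials row-wise
        logw = -0.5 * q
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        np.fill_diagonal(w, 0.0)
        w /= w.sum(axis=1, keepdims=True)
        new_cov = np.einsum("ij,ijk,ijl->kl", w, diffs, diffs) / n
        new_cov = 0.5 * (new_cov + new_cov.T) + RIDGE * np.eye(dim)
        eigvals = np.linalg.eigvalsh(new_cov)
        if eigvals[0] < EIG_FLOOR:
            warnings.warn(
                "covariance nearly singular; regularizing to the eigenvalue "
                "floor (data may be degenerate in some direction)",
                RuntimeWarning,
                stacklevel=2,
            )
            new_cov += (EIG_FLOOR - eigvals[0]) * np.eye(dim)
        delta = np.linalg.norm(new_cov - cov) / max(np.linalg.norm(cov), 1e-300)
        cov = new_cov
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"covariance fixed point not converged in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return BandwidthModel(
        pilot_covariance=cov,
        local_scales=np.ones(n),
        alpha=1.0,
        abramson_enabled=False,
        iterations_used=it,
        converged=converged,
    )


class KDEModel:
    """Evaluable KDE with analytic gradient and Hessian.

    The density is ``f(x) = (1/N) sum_i K(x - Y_i | s_i C)`` with scalar
    scales ``s_i = alpha * lambda_i`` combining the global broadening and the
    per-point Abramson factors.  Because every kernel shares the eigenbasis
    of the pilot covariance, one Cholesky factorization serves all of them.
    """

    def __init__(self, point_set: PointSet, bandwidth: BandwidthModel):
        if bandwidth.local_scales.shape[0] != point_set.n_points:
            raise ValueError("one local scale per data point is required")
        if bandwidth.pilot_covariance.shape[0] != point_set.dim:
            raise ValueError("covariance dimension does not match the data")
        self.point_set = point_set
        self.bandwidth = bandwidth
        cov = bandwidth.pilot_covariance
        c, low = cho_factor(cov)
        self._prec = cho_solve((c, low), np.eye(point_set.dim))  # C^{-1}
        self._logdet = 2.0 * np.sum(np.log(np.diag(c)))
        self._scales = bandwidth.alpha * bandwidth.local_scales  # s_i
        dim = point_set.dim
        # per-kernel log normalization constants
        self._lognorm = -0.5 * (
            dim * np.log(2.0 * np.pi * self._scales) + self._logdet
        )

    @property
    def n_points(self) -> int:
        return self.point_set.n_points

    @property
    def dim(self) -> int:
        return self.point_set.dim

    @property
    def kernel_scale(self) -> float:
        """Largest kernel standard deviation (normalized coordinates).

        Square root of the biggest eigenvalue of the widest per-point
        covariance; optimization steps are capped at a few multiples of
        this so ascents cannot jump across inter-cluster valleys.
        """
        eig_max = float(np.linalg.eigvalsh(self.bandwidth.pilot_covariance)[-1])
        return float(np.sqrt(eig_max * self._scales.max()))

    def kernel_lengths(self, v: np.ndarray) -> float:
        """Length of a displacement in kernel standard deviations.

        Mahalanobis norm under the broadened pilot covariance (the
        per-point factors have geometric mean one and drop out of this
        global metric).  Used to cap optimization steps anisotropically:
        a step of a few kernel lengths stays local in every direction.
        """
        v = np.asarray(v, dtype=float)
        return float(np.sqrt((v @ self._prec @ v) / self.bandwidth.alpha))

    def _kernel_values(self, x: np.ndarray):
        """Per-kernel densities k_i at x, plus the precision-rotated diffs."""
        d = x[None, :] - self.point_set.points  # (N, D)
        u = d @ self._prec  # C^{-1} d  (precision symmetric)
        q = np.einsum("nd,nd->n", d, u)
        k = np.exp(self._lognorm - 0.5 * q / self._scales)
        return k, u

    def evaluate(self, x, derivatives: bool = True):
        """Density, gradient and Hessian of the KDE at ``x``.

        With ``derivatives=False`` only the density is returned.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape[0] != self.dim:
            raise ValueError(
                f"point has dimension {x.shape[0]}, model is {self.dim}-D"
            )
        k, u = self._kernel_values(x)
        n = self.n_points
        density = float(k.sum() / n)
        if not derivatives:
            return density
        ks = k / self._scales
        grad = -(ks @ u) / n
        hess = (
            np.einsum("n,nd,ne->de", ks / self._scales, u, u) - ks.sum() * self._prec
        ) / n
        hess = 0.5 * (hess + hess.T)
        return density, grad, hess

    def density(self, x) -> float:
        return self.evaluate(x, derivatives=False)

    def density_many(self, xs: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Vectorized density over the rows of ``xs`` (grid scans, scoring)."""
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        out = np.empty(xs.shape[0])
        pts = self.point_set.points
        for start in range(0, xs.shape[0], chunk):
            block = xs[start : start + chunk]
            d = block[:, None, :] - pts[None, :, :]
            q = np.einsum("mnd,de,mne->mn", d, self._prec, d)
            logk = self._lognorm[None, :] - 0.5 * q / self._scales[None, :]
            out[start : start + chunk] = np.exp(
                logsumexp(logk, axis=1) - np.log(self.n_points)
            )
        return out

    def density_at_data(self) -> np.ndarray:
        """Density evaluated at every data point."""
        return self.density_many(self.point_set.points)

    def kernel_weights(self, x) -> np.ndarray:
        """Per-kernel contributions k_i / N at ``x`` (they sum to f(x))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k, _ = self._kernel_values(x)
        return k / self.n_points


def abramson_rescale(model: KDEModel) -> BandwidthModel:
    """Abramson local-bandwidth factors from a uniform-covariance pilot KDE.

    Computes the geometric mean ``g`` of the pilot densities at the data and
    sets ``lambda_k = (f(Y_k)/g)^{-1/2}``; the product structure forces the
    geometric mean of the factors to one, so the overall smoothing level is
    preserved while sparse regions broaden and dense regions sharpen.
    """
    dens = model.density_at_data()
    floor = np.finfo(float).tiny
    if np.any(dens <= floor):
        warnings.warn(
            "pilot density underflowed at some data points; flooring",
            RuntimeWarning,
            stacklevel=2,
        )
        dens = np.maximum(dens, floor)
    log_g = np.mean(np.log(dens))
    lam = np.exp(-0.5 * (np.log(dens) - log_g))
    bw = model.bandwidth
    return BandwidthModel(
        pilot_covariance=bw.pilot_covariance,
        local_scales=lam,
        geometric_mean_density=float(np.exp(log_g)),
        alpha=bw.alpha,
        abramson_enabled=True,
        iterations_used=bw.iterations_used,
        converged=bw.converged,
    )
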