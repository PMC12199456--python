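"""Mode seeking: assign every data point to its dominant density maximum.

Each point is used as the start of a safeguarded Newton ascent on the KDE.
The full Newton step is taken only while the Hessian is negative definite
and the density does not decrease; otherwise the climber falls back to
steepest ascent with Armijo backtracking, so the density is non-decreasing
over accepted iterates.  Converged endpoints closer than ``dedup_tol`` are
identified as the same maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kde import KDEModel

logger = logging.getLogger(__name__)

__all__ = ["Maximum", "climb_to_maximum", "assign_points"]

#: gradient-norm convergence tolerance in normalized coordinates
GRAD_TOL = 1e-8
#: endpoints within this Euclidean distance are the same maximum
DEDUP_TOL = 1e-3
MAX_ITER = 200
#: step cap in units of the kernel scale; keeps each climb local so an
#: ill-conditioned Newton step cannot jump across an inter-cluster valley
#: onto a higher, unrelated peak
MAX_STEP_KERNELS = 3.0


@dataclass(eq=False)
class Maximum:
    """A located density maximum and the points whose climbs reached it."""

    location: np.ndarray
    density: float
    member_indices: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def to_dict(self) -> dict:
        return {
            "location": np.asarray(self.location).tolist(),
            "density": float(self.density),
            "size": self.size,
        }


def climb_to_maximum(
    model: KDEModel,
    start,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
):
    """Ascend the KDE from ``start`` to a local maximum.

    Returns ``(location, density, converged)``.  The climb stops when the
    gradient norm drops below ``tol``; a stationary point whose Hessian is
    not negative definite (ridge/saddle/flat) is reported as non-converged.
    """
    x = np.atleast_1d(np.asarray(start, dtype=float)).copy()
    f, g, h = model.evaluate(x)
    if np.linalg.norm(g) < tol:
        return x, f, _is_negative_definite(h)
    for _ in range(max_iter):
        step = None
        eigvals = np.linalg.eigvalsh(h)
        if eigvals[-1] < -1e-12:  # strictly negative definite Hessian
            newton = np.linalg.solve(h, -g)
            if np.dot(newton, g) > 0:  # ascent direction
                step = newton
        if step is None:
            gnorm = np.linalg.norm(g)
            step = g / gnorm * min(0.1, gnorm)  # scaled steepest ascent
            klen = model.kernel_lengths(step)
            if klen > 1.0:  # at most one kernel length per ascent step
                step /= klen
        # anisotropic cap: a Newton step of many kernel lengths would jump
        # across an inter-cluster valley onto an unrelated peak
        klen = model.kernel_lengths(step)
        if klen > MAX_STEP_KERNELS:
            step *= MAX_STEP_KERNELS / klen
        # backtrack until the density does not decrease (Armijo on ascent)
        t = 1.0
        accepted = False
        for _ in range(40):
            x_new = x + t * step
            f_new = model.evaluate(x_new, derivatives=False)
            if f_new >= f + 1e-4 * t * np.dot(g, step) and f_new >= f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # no ascent possible: numerically at a stationary point
        x = x_new
        f, g, h = model.evaluate(x)
        if np.linalg.norm(g) < tol:
            return x, f, _is_negative_definite(h)
    converged = np.linalg.norm(g) < max(tol, 1e-6) and _is_negative_definite(h)
    return x, f, converged


def _is_negative_definite(h: np.ndarray, tol: float = 1e-10) -> bool:
    return bool(np.linalg.eigvalsh(h)[-1] < tol)


def assign_points(
    model: KDEModel,
    dedup_tol: float = DEDUP_TOL,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> list[Maximum]:
    """Climb from every data point and group the endpoints into maxima.

    Returns maxima sorted by decreasing density (ties broken by location),
    whose member sets partition the data point indices.  Non-converged
    climbs are assigned to the located maximum minimizing distance/density.
    """
    pts = model.point_set.points
    n = pts.shape[0]
    endpoints = np.empty_like(pts)
    densities = np.empty(n)
    ok = np.empty(n, dtype=bool)
    for i in range(n):
        loc, dens, conv = climb_to_maximum(model, pts[i], tol=tol, max_iter=max_iter)
        endpoints[i] = loc
        densities[i] = dens
        ok[i] = conv
    if not ok.all():
        logger.warning(
            "%d of %d climbs did not converge to a strict maximum; "
            "assigning them to the nearest located maximum",
            int((~ok).sum()),
            n,
        )

    # deduplicate converged endpoints, highest density first so the
    # representative location of each maximum is its best estimate
    order = np.argsort(-densities, kind="stable")
    maxima: list[Maximum] = []
    pending: list[int] = []
    for i in order:
        if not ok[i]:
            pending.append(i)
            continue
        for m in maxima:
            if np.linalg.norm(endpoints[i] - m.location) < dedup_tol:
                m.member_indices.append(int(i))
                break
        else:
            maxima.append(
                Maximum(
                    location=endpoints[i].copy(),
                    density=float(densities[i]),
                    member_indices=[int(i)],
                )
            )
    if not maxima:
        # every climb failed (pathologically flat density): one cluster
        j = int(np.argmax(densities))
        maxima = [Maximum(endpoints[j].copy(), float(densities[j]), pending)]
        pending = []
    for i in pending:  # density-weighted nearest maximum
        scores = [
            np.linalg.norm(endpoints[i] - m.location) / max(m.density, 1e-300)
            for m in maxima
        ]
        maxima[int(np.argmin(scores))].member_indices.append(int(i))

    maxima = [m for m in maxima if m.member_indices]
    maxima.sort(key=lambda m: (-m.density, tuple(np.asarray(m.location))))
    for m in maxima:
        m.member_indices.sort()
    return maxima
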