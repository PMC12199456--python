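"""Saddle-point search between density maxima and the cluster-merge step.

Two maxima linked by a high pass in the density belong to one cluster.  The
pass (a first-order saddle: exactly one positive Hessian eigenvalue) is
located by eigenvector following: the lowest Hessian eigenvalue and the
matching gradient component are negated, turning the saddle into a maximum
of an implicit surrogate function whose derivatives are available in closed
form, and a damped Newton iteration ascends that surrogate.  Peak and
saddle densities are collected in a merging matrix M; clusters are merged
greedily while the relative pass height mu_ab = M_ab / min(M_aa, M_bb)
exceeds the threshold beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .kde import KDEModel
from .modes import Maximum

logger = logging.getLogger(__name__)

__all__ = [
    "MergeMatrix",
    "smith_transform",
    "cluster_partial_weights",
    "find_saddle",
    "build_merge_matrix",
    "merge_clusters",
    "resolve_clusters",
]

#: number of closest cross-cluster point pairs seeding each saddle search
N_START_PAIRS = 5
#: searches abort where the density falls below this fraction of the top peak
DENSITY_FLOOR_FRACTION = 1e-4
SADDLE_GRAD_TOL = 1e-8
SADDLE_MAX_ITER = 200
MAX_STEP = 0.2


@dataclass
class MergeMatrix:
    """Symmetric matrix of peak densities (diagonal) and saddle densities.

    ``m[a, a]`` is the density at the center of cluster ``a``; ``m[a, b]``
    the density at the located saddle between ``a`` and ``b`` (zero when no
    valid saddle was found, meaning "do not merge directly").
    """

    m: np.ndarray
    pair_status: dict | None = None

    @property
    def n_clusters(self) -> int:
        return self.m.shape[0]

    def mu(self) -> np.ndarray:
        """Relative pass heights mu_ab = M_ab / min(M_aa, M_bb)."""
        diag = np.diag(self.m)
        denom = np.minimum(diag[:, None], diag[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(denom > 0, self.m / denom, 0.0)
        np.fill_diagonal(mu, 0.0)
        return mu

    def to_dict(self) -> dict:
        return {"m": self.m.tolist()}


def smith_transform(gradient: np.ndarray, hessian: np.ndarray):
    """Negate the lowest Hessian eigenvalue and its gradient component.

    Maps a first-order saddle of the density onto a maximum of the implicit
    surrogate surface, so an ascent iteration can find it.  Returns the
    transformed ``(gradient, hessian)``; the surrogate itself is never
    constructed — only its derivatives are needed by the Newton step.
    """
    g = np.atleast_1d(np.asarray(gradient, dtype=float))
    h = np.atleast_2d(np.asarray(hessian, dtype=float))
    if not np.allclose(h, h.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(h)  # ascending
    if h.shape[0] > 1 and abs(eigvals[0] - eigvals[1]) < 1e-10:
        logger.warning(
            "degenerate lowest Hessian eigenvalue; following the first "
            "eigenvector returned by the solver"
        )
    gp = eigvecs.T @ g
    lam = eigvals.copy()
    lam[0] = -lam[0]
    gp[0] = -gp[0]
    h_t = eigvecs @ np.diag(lam) @ eigvecs.T
    g_t = eigvecs @ gp
    return g_t, 0.5 * (h_t + h_t.T)


def cluster_partial_weights(
    model: KDEModel, x, maxima: list[Maximum]
) -> np.ndarray:
    """Per-cluster kernel weight at ``x``; the weights sum to the density."""
    k = model.kernel_weights(x)
    return np.array([k[m.member_indices].sum() for m in maxima])


def _start_points(model: KDEModel, a: Maximum, b: Maximum, n_pairs: int):
    """Centroids of the ``n_pairs`` closest cross-cluster point pairs."""
    pts = model.point_set.points
    pa = pts[a.member_indices]
    pb = pts[b.member_indices]
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    flat = np.argsort(d2, axis=None, kind="stable")[:n_pairs]
    ia, ib = np.unravel_index(flat, d2.shape)
    return 0.5 * (pa[ia] + pb[ib])


def _third_cluster_dominates(weights: np.ndarray, ia: int, ib: int) -> bool:
    """True when some third cluster outweighs a and b combined."""
    w = weights.copy()
    wa, wb = w[ia], w[ib]
    w[[ia, ib]] = -np.inf
    return bool(w.max(initial=-np.inf) > wa + wb)


def _is_index_one(hessian: np.ndarray, tol: float = 1e-12) -> bool:
    eigvals = np.linalg.eigvalsh(hessian)
    return int((eigvals > tol).sum()) == 1


def _following_step(g: np.ndarray, h: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """One damped eigenvector-following step toward a first-order saddle.

    The eigendirection with the largest overlap with ``axis`` (the line
    joining the two maxima, which at the saddle is parallel to the pass
    direction) has its eigenvalue and gradient component flipped, making
    the saddle a stable maximum of the implicit surrogate.  Where the
    flipped Hessian is negative definite the plain Newton step is taken
    (identical to the untransformed Newton step, since flipping both the
    eigenvalue and the gradient component leaves ``-g/lambda`` unchanged);
    elsewhere an eigenvalue shift keeps the step an ascent direction of
    the surrogate, which stops the iteration from running off the ridge.
    The step length is capped in normalized coordinates.
    """
    eigvals, eigvecs = np.linalg.eigh(h)
    follow = int(np.argmax(np.abs(eigvecs.T @ axis)))
    gp = eigvecs.T @ g
    lam = eigvals.copy()
    lam[follow] = -lam[follow]
    gp = gp.copy()
    gp[follow] = -gp[follow]
    if lam.max() < -1e-14:  # surrogate locally concave: pure Newton
        step_p = -gp / lam
    else:  # shift so every denominator is negative (damped ascent)
        tau = lam.max() + 0.1 * np.abs(eigvals).max() + 1e-12
        step_p = -gp / (lam - tau)
    step = eigvecs @ step_p
    norm = np.linalg.norm(step)
    if norm > MAX_STEP:
        step *= MAX_STEP / norm
    return step


def _line_min_along_axis(model, x, loc_a, axis, gap):
    """Density minimum along the line through ``x`` parallel to the axis,
    restricted to the stretch between the two maxima."""
    from scipy.optimize import minimize_scalar

    t0 = np.dot(x - loc_a, axis)
    base = x - t0 * axis

    res = minimize_scalar(
        lambda t: model.evaluate(base + t * axis, derivatives=False),
        bounds=(0.05 * gap, 0.95 * gap),
        method="bounded",
        options={"xatol": 1e-6 * max(gap, 1.0)},
    )
    return base + float(res.x) * axis


def _climb_to_ridge(model, x, axis, floor, max_iter=100):
    """Ascend the density within the hyperplane orthogonal to ``axis``.

    Safeguarded Newton with backtracking, restricted to the subspace
    orthogonal to the line joining the two maxima; lands on the connecting
    ridge, where the subsequent saddle iteration is well conditioned.
    Returns the ridge point, or None when the climb sinks below ``floor``.
    """
    proj = np.eye(x.shape[0]) - np.outer(axis, axis)
    f, g, h = model.evaluate(x)
    for _ in range(max_iter):
        if f < floor:
            return None
        gp = proj @ g
        if np.linalg.norm(gp) < 1e-9:
            return x
        hp = proj @ h @ proj
        eigvals = np.linalg.eigvalsh(hp)
        step = None
        if eigvals[0] < -1e-12 and eigvals[-1] < 1e-12:  # ND on the subspace
            step = proj @ np.linalg.lstsq(hp - 1e-12 * np.eye(len(x)), -gp,
                                          rcond=None)[0]
            if np.dot(step, gp) <= 0:
                step = None
        if step is None:
            step = gp / np.linalg.norm(gp) * 0.05
        norm = np.linalg.norm(step)
        if norm > MAX_STEP:
            step *= MAX_STEP / norm
        t, accepted = 1.0, False
        for _ in range(30):
            x_new = x + t * step
            f_new = model.evaluate(x_new, derivatives=False)
            if f_new >= f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            return x
        x = x_new
        f, g, h = model.evaluate(x)
    return x


def find_saddle(
    model: KDEModel,
    cluster_a: Maximum,
    cluster_b: Maximum,
    all_maxima: list[Maximum],
    n_start_pairs: int = N_START_PAIRS,
    density_floor: float = 0.0,
    tol: float = SADDLE_GRAD_TOL,
    max_iter: int = SADDLE_MAX_ITER,
) -> float:
    """Largest valid first-order-saddle density between two clusters.

    Damped Newton searches on the eigenvector-following surrogate start from
    the centroids of the closest cross-cluster point pairs.  A search is
    aborted (contributing nothing) as soon as a third cluster carries more
    kernel weight than either of the two under consideration, or the density
    falls below ``density_floor``.  A converged endpoint is accepted only if
    its Hessian has exactly one positive eigenvalue.  Returns 0.0 when no
    search produces a valid saddle, which downstream means "no direct merge".
    """
    best, _ = _search_pair(
        model,
        cluster_a,
        cluster_b,
        all_maxima,
        n_start_pairs=n_start_pairs,
        density_floor=density_floor,
        tol=tol,
        max_iter=max_iter,
    )
    return best


def _dominating_third(weights: np.ndarray, ia: int, ib: int):
    """Index of a third cluster outweighing a and b combined, or None."""
    w = weights.copy()
    wa, wb = w[ia], w[ib]
    w[[ia, ib]] = -np.inf
    c = int(np.argmax(w))
    return c if w[c] > wa + wb else None


def _search_pair(
    model,
    cluster_a,
    cluster_b,
    all_maxima,
    n_start_pairs=N_START_PAIRS,
    density_floor=0.0,
    tol=SADDLE_GRAD_TOL,
    max_iter=SADDLE_MAX_ITER,
):
    """Run the per-pair saddle searches; returns (best density, dominators).

    ``dominators`` lists, for every search aborted by the third-cluster
    rule, the index of the dominating cluster; an empty entry (None) marks
    a search that failed for another reason (density floor, left the pass
    region, non-convergence, wrong Hessian index).
    """
    ia = next(i for i, m in enumerate(all_maxima) if m is cluster_a)
    ib = next(i for i, m in enumerate(all_maxima) if m is cluster_b)
    starts = _start_points(model, cluster_a, cluster_b, n_start_pairs)
    loc_a, loc_b = cluster_a.location, cluster_b.location
    gap = np.linalg.norm(loc_b - loc_a)
    axis = (loc_b - loc_a) / max(gap, 1e-300)
    best = 0.0
    dominators: list[int | None] = []
    for x0 in starts:
        x = x0.copy()
        aborted = False
        # alternate a bounded line minimization along the inter-maxima axis
        # with an orthogonal ridge climb; this brackets the pass before the
        # Newton polish and keeps the iterate between the two peaks
        for _ in range(4):
            x = _line_min_along_axis(model, x, loc_a, axis, gap)
            x = _climb_to_ridge(model, x, axis, density_floor)
            if x is None:
                dominators.append(None)
                aborted = True
                break
            weights = cluster_partial_weights(model, x, all_maxima)
            third = _dominating_third(weights, ia, ib)
            if third is not None:
                dominators.append(third)
                aborted = True
                break
        if aborted:
            continue
        bracket = x.copy()
        found = None
        geometric_failure = False  # left the region / no convergence
        for _ in range(max_iter):
            f, g, h = model.evaluate(x)
            if f < density_floor:
                dominators.append(None)
                break
            t = np.dot(x - loc_a, axis)
            if not -0.1 * gap <= t <= 1.1 * gap:  # left the pass region
                geometric_failure = True
                break
            weights = cluster_partial_weights(model, x, all_maxima)
            third = _dominating_third(weights, ia, ib)
            if third is not None:
                dominators.append(third)
                break
            if np.linalg.norm(g) < tol:
                if _is_index_one(h):
                    found = f
                else:
                    geometric_failure = True
                break
            x = x + _following_step(g, h, axis)
        else:
            geometric_failure = True  # max_iter exhausted
        if found is None and geometric_failure:
            # the Newton polish wandered off (curved ridges do this); the
            # bracketed mountain-pass point is itself a saddle estimate —
            # accept it when it is near-stationary (relative density change
            # over one kernel length below 5%) with the first-order
            # Hessian signature
            fb, gb, hb = model.evaluate(bracket)
            near_stationary = (
                np.linalg.norm(gb) * model.kernel_scale <= 0.05 * fb
            )
            if fb >= density_floor and near_stationary and _is_index_one(hb):
                found = fb
            else:
                dominators.append(None)
        if found is not None and found > best:
            best = found
    return best, dominators


def _adjacent(model, maxima, ia, ib, starts, floor):
    """Adjacency screen: clusters are adjacent when a and b jointly dominate
    the kernel weights at at least one seed centroid.  Returns
    ``(adjacent, dominators)`` with the dominating third cluster per
    centroid; domination is only assessed where the density is above the
    floor — in essentially empty regions the weight ordering is noise, so
    such centroids count as a plain (non-blocked) failure."""
    dominators = []
    adjacent = False
    for x in starts:
        weights = cluster_partial_weights(model, x, maxima)
        if weights.sum() < floor:
            dominators.append(None)
            continue
        third = _dominating_third(weights, ia, ib)
        dominators.append(third)
        if third is None:
            adjacent = True
    return adjacent, dominators


def build_merge_matrix(
    model: KDEModel,
    maxima: list[Maximum],
    n_start_pairs: int = N_START_PAIRS,
    density_floor_fraction: float = DENSITY_FLOOR_FRACTION,
) -> MergeMatrix:
    """Peak densities on the diagonal, saddle densities off it.

    Saddle searches run only between adjacent cluster pairs (pairs among
    whose seed centroids the two clusters jointly dominate the kernel
    weights); all other off-diagonal entries stay zero.  Located saddle
    densities are capped at the lower of the two peaks so the relative pass
    height mu never exceeds one.  Each pair's outcome is recorded in
    ``pair_status``: ``("found", None)``, ``("blocked", dominator)`` when
    every search was cut off by a dominating third cluster, or
    ``("failed", None)``.
    """
    k = len(maxima)
    m = np.zeros((k, k))
    for i, mx in enumerate(maxima):
        m[i, i] = mx.density
    floor = density_floor_fraction * max((mx.density for mx in maxima), default=0.0)
    status: dict = {}
    for i in range(k):
        for j in range(i + 1, k):
            starts = _start_points(model, maxima[i], maxima[j], n_start_pairs)
            adjacent, screen_doms = _adjacent(model, maxima, i, j, starts, floor)
            if not adjacent:
                dom = _modal(screen_doms)
                status[(i, j)] = ("blocked", dom) if dom is not None else (
                    "failed",
                    None,
                )
                continue
            s, doms = _search_pair(
                model,
                maxima[i],
                maxima[j],
                maxima,
                n_start_pairs=n_start_pairs,
                density_floor=floor,
            )
            if s > 0:
                status[(i, j)] = ("found", None)
            elif doms and all(d is not None for d in doms):
                status[(i, j)] = ("blocked", _modal(doms))
            else:
                status[(i, j)] = ("failed", None)
            cap = min(m[i, i], m[j, j])
            if s > cap:
                logger.info(
                    "saddle density %.3g above the lower peak %.3g for pair "
                    "(%d, %d); capping",
                    s,
                    cap,
                    i,
                    j,
                )
                s = cap
            m[i, j] = m[j, i] = s
    return MergeMatrix(m=m, pair_status=status)


def _modal(values):
    """Most frequent non-None value (ties by first occurrence)."""
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    counts: dict = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    return max(counts, key=lambda v: (counts[v], -vals.index(v)))


def merge_clusters(merge_matrix: MergeMatrix, beta: float):
    """Greedy merging of cluster pairs by relative pass height.

    Repeatedly merges the pair with the highest ``mu_ab = M_ab /
    min(M_aa, M_bb)`` while ``mu_ab > beta``; after each merge both
    diagonals are raised to ``max(M_aa, M_bb)`` and the used off-diagonal is
    zeroed, which stops a low-density cluster from indirectly chaining two
    high-density ones together.  Returns ``(mapping, history)`` where
    ``mapping`` sends each original cluster index to its merged-group index
    (groups numbered by their lowest original member) and ``history`` is the
    ordered list of executed merges ``(a, b, mu_ab)``.
    """
    if not 0.0 < beta < 1.0:
        raise ParameterError("beta must lie strictly between 0 and 1")
    m = merge_matrix.m.copy()
    k = m.shape[0]
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    history: list[tuple[int, int, float]] = []
    work = MergeMatrix(m=m)
    while True:
        mu = work.mu()
        iu = np.triu_indices(k, 1)
        if iu[0].size == 0:
            break
        vals = mu[iu]
        best = vals.max(initial=0.0)
        if best <= beta:
            break
        # ties: lowest a index, then lowest b index
        cand = np.flatnonzero(np.isclose(vals, best))
        a, b = iu[0][cand[0]], iu[1][cand[0]]
        history.append((int(a), int(b), float(best)))
        top = max(m[a, a], m[b, b])
        m[a, a] = m[b, b] = top
        m[a, b] = m[b, a] = 0.0
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = [find(i) for i in range(k)]
    order = sorted(set(roots))
    relabel = {r: i for i, r in enumerate(order)}
    mapping = {i: relabel[roots[i]] for i in range(k)}
    return mapping, history


def _regroup(maxima: list[Maximum], mapping: dict) -> list[Maximum]:
    """Collapse maxima into merged groups; the representative of a group is
    its densest member, and groups are re-sorted by descending density."""
    groups: dict = {}
    for idx, m in enumerate(maxima):
        groups.setdefault(mapping[idx], []).append(m)
    merged = []
    for g in sorted(groups):
        members = groups[g]
        rep = max(members, key=lambda m: m.density)
        idxs = sorted(i for m in members for i in m.member_indices)
        merged.append(Maximum(rep.location.copy(), rep.density, idxs))
    merged.sort(key=lambda m: (-m.density, tuple(np.asarray(m.location))))
    return merged


def resolve_clusters(
    model: KDEModel,
    maxima: list[Maximum],
    beta: float,
    n_start_pairs: int = N_START_PAIRS,
    density_floor_fraction: float = DENSITY_FLOOR_FRACTION,
    matrix: MergeMatrix | None = None,
):
    """Full merge stage: matrix build, greedy merging, orphan absorption.

    After the merge loop, a group whose every saddle search ended in a
    third-cluster abort (none found a saddle, none failed for any other
    reason) has no direct pass to anywhere only because some other cluster
    dominates its entire surroundings — it lies inside that cluster's
    territory, so it is absorbed into the group of its modal dominator.
    Clusters separated by genuinely low or vanishing density keep at least
    one non-blocked (failed or low-saddle) search and are never absorbed.

    Returns ``(merged_maxima, matrix, history, absorbed)`` where
    ``absorbed`` lists ``(orphan_group_member, target_group_member)`` pairs
    in pre-merge indices.
    """
    if matrix is None:
        matrix = build_merge_matrix(
            model,
            maxima,
            n_start_pairs=n_start_pairs,
            density_floor_fraction=density_floor_fraction,
        )
    mapping, history = merge_clusters(matrix, beta)
    status = matrix.pair_status or {}

    absorbed: list[tuple[int, int]] = []
    changed = True
    while changed:
        changed = False
        groups: dict[int, list[int]] = {}
        for k, g in mapping.items():
            groups.setdefault(g, []).append(k)
        if len(groups) < 2:
            break
        group_ids = sorted(groups)
        group_members = {
            g: [i for k in groups[g] for i in maxima[k].member_indices]
            for g in group_ids
        }
        floor = DENSITY_FLOOR_FRACTION * max(m.density for m in maxima)
        for g in group_ids:
            members = groups[g]
            verdicts = [
                (j, status.get(tuple(sorted((i, j)))))
                for i in members
                for j in range(len(maxima))
                if mapping[j] != g
            ]
            # a located direct pass (even one below beta) marks a genuine
            # neighbor boundary: the group is not inside anyone's territory
            if any(v is not None and v[0] == "found" for _, v in verdicts):
                continue
            # enclosure evidence: a search toward cluster j cut off by a
            # member of j's own merged group; all such evidence must point
            # at a single target group
            targets = set()
            for j, v in verdicts:
                if v is None or v[0] != "blocked" or v[1] is None:
                    continue
                if mapping[v[1]] == mapping[j]:
                    targets.add(mapping[j])
            if not targets:
                continue
            # locality check: the target must actually carry density at the
            # orphan's summit (a satellite rides on the target's body; a
            # separate cluster across an empty region does not); with
            # several candidates the one with the most weight there wins
            rep = max((maxima[k] for k in members), key=lambda m: m.density)
            kernel_w = model.kernel_weights(rep.location)
            target_w = {
                t: kernel_w[group_members[t]].sum() for t in sorted(targets)
            }
            target = max(target_w, key=target_w.get)
            if target_w[target] < floor:
                continue
            absorbed.append((members[0], groups[target][0]))
            logger.info(
                "absorbing cluster group %d into group %d (enclosed by "
                "that group's territory)",
                g,
                target,
            )
            for k in members:
                mapping[k] = target
            changed = True
            break  # regroup before scanning further
    # renumber groups contiguously
    relabel = {g: i for i, g in enumerate(sorted(set(mapping.values())))}
    mapping = {k: relabel[g] for k, g in mapping.items()}
    merged = _regroup(maxima, mapping)
    return merged, matrix, history, absorbed
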