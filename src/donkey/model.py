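"""Model/results interface for the full clustering pipeline.

``KDEClustering`` is built from a data matrix and a handful of tuning
parameters; ``fit()`` runs the whole pipeline — feature normalization,
leave-one-out covariance optimization, Abramson local rescaling, mode
seeking, saddle-point merging, optional outlier flagging — and returns a
``KDEClusteringResults`` holding the labels, the located maxima, the
merging matrix and every intermediate needed for cheap warm restarts:
changing ``alpha`` restarts at the maxima search (the optimized covariance
is independent of the broadening), changing ``beta`` restarts at the merge
loop, and changing ``gamma`` only recomputes the outlier flags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import MissingIntermediatesError, ParameterError
from .kde import BandwidthModel, KDEModel, PointSet, abramson_rescale, optimize_covariance
from .merging import MergeMatrix, resolve_clusters
from .modes import assign_points

__all__ = ["RunConfig", "KDEClustering", "KDEClusteringResults", "run_donkey"]

DEFAULT_BETA = float(np.exp(-1.0))


@dataclass
class RunConfig:
    """Tuning parameters of a clustering run.

    ``alpha`` broadens every kernel covariance by a common factor (1 leaves
    the optimized bandwidth untouched); ``beta`` is the relative pass height
    above which adjacent clusters merge (default ``1/e``, the drop of a
    Gaussian one standard deviation from its center); ``gamma`` flags point
    ``i`` of cluster ``c`` as an outlier when ``f(Y_i)/M_cc < gamma``
    (0 disables flagging).
    """

    alpha: float = 1.0
    beta: float = DEFAULT_BETA
    gamma: float = 0.0
    abramson_enabled: bool = True
    normalize: bool = True
    cov_tol: float = 1e-6
    cov_max_iter: int = 500
    seed: int | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if not 0.0 < self.beta < 1.0:
            raise ParameterError("beta must lie strictly in (0, 1)")
        if self.gamma < 0:
            raise ParameterError("gamma must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


class KDEClustering:
    """Density-based clustering model for a fixed data matrix.

    Parameters
    ----------
    data : array_like or DataFrame, shape (N, D)
        One row per observation, all columns numeric.
    alpha, beta, gamma, abramson, normalize
        See :class:`RunConfig`.

    Examples
    --------
    >>> model = KDEClustering(points)
    >>> res = model.fit()
    >>> res.labels
    array([0, 0, 1, ...])
    """

    def __init__(
        self,
        data,
        alpha: float = 1.0,
        beta: float = DEFAULT_BETA,
        gamma: float = 0.0,
        abramson: bool = True,
        normalize: bool = True,
        seed: int | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            self.feature_names = list(data.columns)
            data = data.to_numpy(dtype=float)
        else:
            data = np.asarray(data, dtype=float)
            if data.ndim == 1:
                data = data[:, None]
            self.feature_names = [f"x{i}" for i in range(data.shape[1])]
        self.data = data
        self.config = RunConfig(
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            abramson_enabled=abramson,
            normalize=normalize,
            seed=seed,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "KDEClustering":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "KDEClustering":
        """Build a model from a delimited text file (comma or tab).

        A single non-numeric first row is treated as a header.
        """
        df = pd.read_csv(path, sep=None, engine="python")
        try:
            df.columns.astype(float)
        except (TypeError, ValueError):
            pass  # genuine header row
        else:  # header was actually data; reread without one
            df = pd.read_csv(path, sep=None, engine="python", header=None)
        return cls(df.astype(float), **kwargs)

    def fit(self) -> "KDEClusteringResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        point_set = PointSet(self.data, normalize=cfg.normalize)
        pilot_bw = optimize_covariance(
            point_set, tol=cfg.cov_tol, max_iter=cfg.cov_max_iter
        )
        if cfg.abramson_enabled:
            pilot_model = KDEModel(point_set, pilot_bw)
            bandwidth = abramson_rescale(pilot_model)
        else:
            bandwidth = pilot_bw
        return _finish_from_bandwidth(self, point_set, bandwidth)


def _finish_from_bandwidth(
    model: KDEClustering, point_set: PointSet, bandwidth: BandwidthModel
) -> "KDEClusteringResults":
    """Maxima search onward; the entry point for warm alpha restarts."""
    cfg = model.config
    bw = BandwidthModel(
        pilot_covariance=bandwidth.pilot_covariance,
        local_scales=bandwidth.local_scales,
        geometric_mean_density=bandwidth.geometric_mean_density,
        alpha=cfg.alpha,
        abramson_enabled=bandwidth.abramson_enabled,
        iterations_used=bandwidth.iterations_used,
        converged=bandwidth.converged,
    )
    kde = KDEModel(point_set, bw)
    maxima = assign_points(kde)
    return _finish_from_maxima(model, point_set, bandwidth, kde, maxima)


def _finish_from_maxima(
    model, point_set, bandwidth, kde, maxima, matrix=None
) -> "KDEClusteringResults":
    """Merge stage onward; the entry point for warm beta restarts (which
    pass the stored merging matrix so no saddle search is repeated)."""
    cfg = model.config
    merged, merge_matrix, history, absorbed = resolve_clusters(
        kde, maxima, cfg.beta, matrix=matrix
    )
    n = point_set.n_points
    labels = np.empty(n, dtype=int)
    for g, mx in enumerate(merged):
        labels[mx.member_indices] = g
    cluster_peak = np.array([mx.density for mx in merged])
    point_density = kde.density_at_data()
    flags = (
        point_density / cluster_peak[labels] < cfg.gamma
        if cfg.gamma > 0
        else np.zeros(n, dtype=bool)
    )
    return KDEClusteringResults(
        model=model,
        point_set=point_set,
        bandwidth=bandwidth,
        kde=kde,
        premerge_maxima=maxima,
        merge_matrix=merge_matrix,
        labels=labels,
        outlier_flags=np.asarray(flags, dtype=bool),
        maxima=merged,
        merge_history=history,
        point_density=point_density,
        cluster_peak_density=cluster_peak,
    )


@dataclass
class KDEClusteringResults:
    """Fitted clustering: labels, maxima, merge bookkeeping, diagnostics."""

    model: KDEClustering
    point_set: PointSet
    bandwidth: BandwidthModel  # pre-broadening (alpha applied at use time)
    kde: KDEModel
    premerge_maxima: list
    merge_matrix: MergeMatrix
    labels: np.ndarray
    outlier_flags: np.ndarray
    maxima: list
    merge_history: list = field(default_factory=list)
    point_density: np.ndarray | None = None
    cluster_peak_density: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.maxima)

    @property
    def params(self) -> RunConfig:
        return self.model.config

    def cluster_centers(self) -> np.ndarray:
        """Cluster-center locations in the original feature units."""
        return np.array(
            [self.point_set.denormalize(m.location) for m in self.maxima]
        )

    # ---------------------------------------------------------------- rerun
    def rerun(self, alpha=None, beta=None, gamma=None) -> "KDEClusteringResults":
        """Recompute with changed parameters, reusing stored intermediates.

        A new ``alpha`` restarts at the maxima search (the optimized
        covariance does not depend on the broadening); a new ``beta``
        restarts at the merge loop; a new ``gamma`` only recomputes the
        outlier flags.  Results are identical to a cold run with the same
        parameters.
        """
        if self.kde is None or self.merge_matrix is None:
            raise MissingIntermediatesError(
                "stored intermediates are missing; re-run fit() from scratch"
            )
        import copy

        new_model = copy.copy(self.model)
        cfg = RunConfig.from_dict(self.model.config.to_dict())
        if alpha is not None:
            cfg.alpha = alpha
        if beta is not None:
            cfg.beta = beta
        if gamma is not None:
            cfg.gamma = gamma
        new_model.config = cfg
        if alpha is not None and alpha != self.model.config.alpha:
            return _finish_from_bandwidth(new_model, self.point_set, self.bandwidth)
        if beta is not None and beta != self.model.config.beta:
            return _finish_from_maxima(
                new_model,
                self.point_set,
                self.bandwidth,
                self.kde,
                self.premerge_maxima,
                matrix=self.merge_matrix,
            )
        # gamma-only change: reuse everything, recompute flags
        out = copy.copy(self)
        out.model = new_model
        flags = (
            self.point_density / self.cluster_peak_density[self.labels] < cfg.gamma
            if cfg.gamma > 0
            else np.zeros(self.labels.shape[0], dtype=bool)
        )
        out.outlier_flags = np.asarray(flags, dtype=bool)
        return out

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.model.config
        bw = self.bandwidth
        lines = [
            "KDE Clustering Results",
            "=" * 58,
            f"Observations:        {self.point_set.n_points}",
            f"Features (kept):     {self.point_set.dim}",
            f"alpha / beta / gamma: {cfg.alpha:g} / {cfg.beta:.6f} / {cfg.gamma:g}",
            f"Abramson rescaling:  {'on' if bw.abramson_enabled else 'off'}",
            f"Covariance iterations: {bw.iterations_used}"
            f" (converged: {bw.converged})",
            f"Maxima before merge: {len(self.premerge_maxima)}",
            f"Clusters after merge: {self.n_clusters}",
            f"Merges executed:     {len(self.merge_history)}",
            f"Outliers flagged:    {int(self.outlier_flags.sum())}",
            "-" * 58,
            f"{'cluster':>8} {'size':>6} {'peak density':>14}",
        ]
        for g, m in enumerate(self.maxima):
            lines.append(f"{g:>8} {m.size:>6} {m.density:>14.5g}")
        return "\n".join(lines)

    # ---------------------------------------------------------------- plot
    def plot(self, ax=None):
        """Scatter of the first two features colored by cluster label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.data[:, :2]
        ax.scatter(x[:, 0], x[:, 1], c=self.labels, s=12, cmap="tab10")
        if self.outlier_flags.any():
            o = self.outlier_flags
            ax.scatter(x[o, 0], x[o, 1], facecolors="none", edgecolors="k", s=40)
        centers = self.cluster_centers()
        ax.scatter(centers[:, 0], centers[:, 1], marker="x", c="k", s=80)
        ax.set_xlabel(self.model.feature_names[0])
        if x.shape[1] > 1:
            ax.set_ylabel(self.model.feature_names[1])
        return ax

    # ----------------------------------------------------------------- i/o
    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "outlier_flags": self.outlier_flags.tolist(),
            "maxima": [
                {**m.to_dict(), "location_original": self.point_set.denormalize(
                    m.location
                ).tolist()}
                for m in self.maxima
            ],
            "premerge_maxima": [m.to_dict() for m in self.premerge_maxima],
            "merge_matrix": self.merge_matrix.to_dict(),
            "merge_history": [list(h) for h in self.merge_history],
            "params": self.model.config.to_dict(),
            "normalization_map": self.point_set.to_dict(),
            "bandwidth": self.bandwidth.to_dict(),
            "point_density": self.point_density.tolist(),
            "points_normalized": self.point_set.points.tolist(),
            "seed": self.model.config.seed,
            "versions": {"donkey": __version__},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_donkey(points, config: RunConfig | None = None, **kwargs) -> KDEClusteringResults:
    """One-call pipeline: build a :class:`KDEClustering` and fit it.

    ``config`` may be a :class:`RunConfig`; keyword arguments override its
    fields (``alpha``, ``beta``, ``gamma``, ``abramson``, ``normalize``,
    ``seed``).
    """
    cfg = config.to_dict() if config is not None else {}
    cfg.update(kwargs)
    model = KDEClustering(
        points,
        alpha=cfg.get("alpha", 1.0),
        beta=cfg.get("beta", DEFAULT_BETA),
        gamma=cfg.get("gamma", 0.0),
        abramson=cfg.get("abramson", cfg.get("abramson_enabled", True)),
        normalize=cfg.get("normalize", True),
        seed=cfg.get("seed"),
    )
    return model.fit()
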