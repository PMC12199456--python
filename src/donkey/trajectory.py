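"""Frame-by-frame clustering of molecular-dynamics trajectory ensembles.

Workflow: read an ensemble of multi-frame XYZ trajectories on a common
time grid, compute internal-coordinate features of four key atoms (wing
separation, rhombicity, wing length — the standard descriptors of the
norbornadiene/quadricyclane interconversion) plus their rates of change,
reduce the six-dimensional per-frame matrix by PCA (keeping components
whose explained-variance ratio exceeds 1%), run the density clustering
independently at a fixed frame cadence, and finally group trajectories
into channels — sets that cluster identically at every chosen checkpoint
frame.  A synthetic branching-ensemble generator with ground-truth channel
labels supports end-to-end testing; real ensembles of this kind come from
surface-hopping simulations and are not bundled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, ParameterError, TrajectoryFormatError
from .model import run_donkey

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryEnsemble",
    "FeatureSeries",
    "ChannelAssignment",
    "read_trajectories",
    "write_xyz",
    "compute_features",
    "reduce_features",
    "cluster_frames",
    "assemble_channels",
    "make_branching_ensemble",
]


@dataclass
class TrajectoryEnsemble:
    """Cartesian coordinates of many trajectories on one time grid.

    ``coords`` has shape ``(n_traj, n_frames, n_atoms, 3)`` in Angstrom;
    ``times`` is the shared uniform grid in femtoseconds.
    """

    coords: np.ndarray
    times: np.ndarray
    atom_labels: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[3] != 3:
            raise TrajectoryFormatError(
                "coords must have shape (n_traj, n_frames, n_atoms, 3)"
            )
        if self.times.shape[0] != self.coords.shape[1]:
            raise TrajectoryFormatError("time grid does not match frame count")
        if self.times.size > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0]):
                raise TrajectoryFormatError("time grid must be uniform and increasing")

    @property
    def n_traj(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[2]


@dataclass
class FeatureSeries:
    """Internal-coordinate features and their time derivatives.

    ``features`` and ``rates`` have shape ``(n_traj, n_frames, 3)`` holding
    (wing separation, rhombicity, wing length) in Angstrom and Angstrom/fs.
    """

    features: np.ndarray
    rates: np.ndarray
    times: np.ndarray
    atom_indices: tuple

    FEATURE_NAMES = ("wing_separation", "rhombicity", "wing_length")

    def frame_matrix(self, frame_index: int) -> np.ndarray:
        """Six-column (features + rates) matrix for one frame."""
        return np.hstack(
            [self.features[:, frame_index, :], self.rates[:, frame_index, :]]
        )


@dataclass
class ChannelAssignment:
    """Trajectories grouped by their tuple of checkpoint cluster labels."""

    checkpoint_times: tuple
    trajectory_tuples: list  # per-trajectory tuple of labels
    channels: dict = field(default_factory=dict)  # tuple -> member indices

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_labels(self) -> np.ndarray:
        """Integer channel id per trajectory, numbered by descending size."""
        order = sorted(
            self.channels, key=lambda t: (-len(self.channels[t]), t)
        )
        index = {t: i for i, t in enumerate(order)}
        return np.array([index[t] for t in self.trajectory_tuples])

    def member_counts(self) -> list:
        return sorted((len(v) for v in self.channels.values()), reverse=True)


# ----------------------------------------------------------------- XYZ I/O


def _diagnose_xyz(path: str) -> None:
    """Re-scan an unparseable XYZ file to report the offending line."""
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        try:
            n_atoms = int(stripped)
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: line {i + 1}: expected an atom count, got {stripped!r}"
            ) from None
        i += 2  # skip comment line
        for j in range(n_atoms):
            if i + j >= len(lines):
                raise TrajectoryFormatError(
                    f"{path}: truncated frame starting near line {i - 1}"
                )
            parts = lines[i + j].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}: line {i + j + 1}: malformed coordinate line"
                )
            try:
                [float(p) for p in parts[1:4]]
            except ValueError:
                raise TrajectoryFormatError(
                    f"{path}: line {i + j + 1}: malformed coordinate line"
                ) from None
        i += n_atoms


def read_trajectories(paths, dt: float = 0.5, t0: float = 0.0) -> TrajectoryEnsemble:
    """Read one multi-frame XYZ file per trajectory into an ensemble.

    All files must share atom count, atom ordering and frame count; the
    uniform time grid is declared through ``dt`` (fs) and ``t0``.
    """
    import MDAnalysis as mda

    coords = []
    labels = None
    for path in paths:
        path = str(path)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(path, format="XYZ")
                frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
                names = [a.name for a in u.atoms]
        except TrajectoryFormatError:
            raise
        except Exception:
            _diagnose_xyz(path)  # raises with a line number when it can
            raise TrajectoryFormatError(f"{path}: unreadable XYZ file") from None
        if labels is None:
            labels = names
            n_atoms, n_frames = frames.shape[1], frames.shape[0]
        else:
            if frames.shape[1] != n_atoms:
                raise TrajectoryFormatError(
                    f"{path}: atom count {frames.shape[1]} differs from "
                    f"{n_atoms} in the first file"
                )
            if frames.shape[0] != n_frames:
                raise TrajectoryFormatError(
                    f"{path}: frame count {frames.shape[0]} differs from "
                    f"{n_frames} in the first file"
                )
        coords.append(frames)
    if not coords:
        raise TrajectoryFormatError("no trajectory files given")
    coords = np.asarray(coords, dtype=float)
    times = t0 + dt * np.arange(coords.shape[1])
    return TrajectoryEnsemble(coords=coords, times=times, atom_labels=labels)


def write_xyz(path, coords: np.ndarray, atom_labels) -> None:
    """Write one trajectory ``(n_frames, n_atoms, 3)`` as multi-frame XYZ."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.XYZ import XYZWriter

    coords = np.asarray(coords, dtype=float)
    n_frames, n_atoms, _ = coords.shape
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", list(atom_labels))
    u.add_TopologyAttr("elements", list(atom_labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with XYZWriter(str(path), n_atoms=n_atoms) as w:
            for f in range(n_frames):
                u.atoms.positions = coords[f]
                w.write(u.atoms)


# ---------------------------------------------------------------- features


def _dist(coords, a, b):
    return np.linalg.norm(coords[..., a, :] - coords[..., b, :], axis=-1)


def compute_features(ensemble: TrajectoryEnsemble, atoms=(0, 1, 2, 3)) -> FeatureSeries:
    """Wing separation, rhombicity, wing length and their rates of change.

    With the four key atoms ``(C1, C2, C3, C4)``: wing separation is
    ``(R12 + R34)/2``, rhombicity the signed difference ``R13 - R24``, and
    wing length ``(R14 + R23)/2``.  Rates are central finite differences on
    the time grid (one-sided at the ends).
    """
    a1, a2, a3, a4 = atoms
    n_atoms = ensemble.n_atoms
    for a in atoms:
        if not 0 <= a < n_atoms:
            raise ParameterError(f"atom index {a} out of range (n_atoms={n_atoms})")
    if ensemble.n_frames < 2:
        raise InsufficientDataError("rates of change require at least two frames")
    c = ensemble.coords
    sep = 0.5 * (_dist(c, a1, a2) + _dist(c, a3, a4))
    rhomb = _dist(c, a1, a3) - _dist(c, a2, a4)
    length = 0.5 * (_dist(c, a1, a4) + _dist(c, a2, a3))
    features = np.stack([sep, rhomb, length], axis=-1)
    rates = np.gradient(features, ensemble.times, axis=1)
    return FeatureSeries(
        features=features, rates=rates, times=ensemble.times, atom_indices=tuple(atoms)
    )


def reduce_features(frame_matrix: np.ndarray, evr_threshold: float = 0.01) -> np.ndarray:
    """Keep the principal components with explained-variance ratio above 1%.

    Plain eigendecomposition of the covariance of the mean-centered
    columns, no whitening; the leading component is always kept, so the
    output has at least one column.  The reduction is recomputed from
    scratch for every clustered frame.
    """
    x = np.asarray(frame_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InsufficientDataError("PCA needs a matrix with at least two rows")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    total = eigvals.sum()
    if total <= 0:
        warnings.warn("zero-variance frame matrix; returning a single zero column",
                      RuntimeWarning, stacklevel=2)
        return np.zeros((x.shape[0], 1))
    evr = eigvals / total
    keep = max(1, int((evr > evr_threshold).sum()))
    return centered @ eigvecs[:, :keep]


# ------------------------------------------------------------- per-frame


def cluster_frames(
    series: FeatureSeries,
    frame_interval: float = 5.0,
    evr_threshold: float = 0.01,
    **donkey_params,
) -> dict:
    """Run the clustering independently at a fixed time cadence.

    At every selected frame the per-trajectory six-vector matrix (features
    plus rates) is assembled, PCA-reduced, and clustered with the full
    pipeline (feature normalization happens inside the pipeline).  Returns
    an ordered mapping ``time -> labels`` (per-trajectory integer labels);
    the fitted results objects are available under ``time`` in the
    ``.results`` attribute of the returned dict.
    """
    times = series.times
    dt = times[1] - times[0] if times.size > 1 else 1.0
    stride = max(1, int(round(frame_interval / dt)))
    out = _FrameResults()
    for fi in range(0, times.size, stride):
        matrix = series.frame_matrix(fi)
        if np.allclose(matrix.std(axis=0), 0.0):
            # all trajectories coincide at this frame: a single cluster
            out[float(times[fi])] = np.zeros(matrix.shape[0], dtype=int)
            out.results[float(times[fi])] = None
            continue
        reduced = reduce_features(matrix, evr_threshold=evr_threshold)
        res = run_donkey(reduced, **donkey_params)
        out[float(times[fi])] = res.labels
        out.results[float(times[fi])] = res
    return out


class _FrameResults(dict):
    """``time -> labels`` mapping that also carries the results objects."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.results = {}


def assemble_channels(per_frame_labels: dict, checkpoint_times) -> ChannelAssignment:
    """Group trajectories that cluster identically at every checkpoint.

    ``per_frame_labels`` maps time to a per-trajectory label vector (the
    output of :func:`cluster_frames`).  Each trajectory is reduced to its
    tuple of labels at the checkpoint times; a channel is a distinct tuple.
    """
    checkpoint_times = tuple(float(t) for t in checkpoint_times)
    for t in checkpoint_times:
        if t not in per_frame_labels:
            raise ParameterError(
                f"no clustering result at checkpoint time {t}; "
                f"available times: {sorted(per_frame_labels)}"
            )
    stacked = np.stack([np.asarray(per_frame_labels[t]) for t in checkpoint_times])
    tuples = [tuple(int(v) for v in stacked[:, j]) for j in range(stacked.shape[1])]
    channels: dict = {}
    for j, tup in enumerate(tuples):
        channels.setdefault(tup, []).append(j)
    return ChannelAssignment(
        checkpoint_times=checkpoint_times,
        trajectory_tuples=tuples,
        channels=channels,
    )


# ------------------------------------------------------ synthetic ensemble


def default_branch_templates(times: np.ndarray, branch_times=(35.0, 55.0)):
    """Four smooth feature-space paths that bifurcate twice.

    All paths start at a norbornadiene-like geometry (wing separation
    2.45 A, rhombicity 0, wing length 1.55 A).  At the first branch time
    the rhombicity splits to +-0.8 A; at the second, the wing separation
    either returns toward 2.45 A (reactant-like) or drops to 1.65 A
    (product-like).  Returned as an array of shape (4, n_frames, 3).
    """
    t = np.asarray(times, dtype=float)
    b1, b2 = branch_times

    def ramp(center, width=4.0):
        return 0.5 * (1.0 + np.tanh((t - center) / width))

    r1 = ramp(b1)
    r2 = ramp(b2)
    sep_base = 2.45 - 0.55 * ramp(b1 - 10.0, 8.0)  # initial compression
    templates = []
    for rho_sign in (+1.0, -1.0):
        for product in (False, True):
            rho = rho_sign * 0.8 * r1
            if product:
                sep = sep_base - 0.25 * r2
            else:
                sep = sep_base + 0.55 * r2
            wing = 1.55 + 0.12 * r1 - (0.10 if product else 0.0) * r2
            templates.append(np.stack([sep, rho, wing], axis=-1))
    return np.asarray(templates)


def _shear_offset(sep, length, rhomb):
    """Wing-frame shear realizing a signed rhombicity.

    Closed form ``u = r sqrt(q - r^2/4) / (2 l)`` with ``q = s^2 + l^2``;
    written without differences of near-equal squares so it stays accurate
    for tiny rhombicity.
    """
    q = sep**2 + length**2
    return rhomb * np.sqrt(np.maximum(q - 0.25 * rhomb**2, 0.0)) / (2.0 * length)


def features_to_geometry(features: np.ndarray) -> np.ndarray:
    """Planar four-atom geometries realizing given feature triples.

    The four carbons form a sheared trapezoid: wings C1-C4 and C2-C3 of
    length ``l``, cross distances R12 = R34 = ``s``, and a shear of the
    second wing along the wing axis that produces the requested signed
    diagonal difference R13 - R24.  Input shape ``(..., 3)``; output shape
    ``(..., 4, 3)``.
    """
    f = np.asarray(features, dtype=float)
    sep, rhomb, length = f[..., 0], f[..., 1], f[..., 2]
    u = _shear_offset(sep, length, rhomb)
    d = np.sqrt(np.maximum(sep**2 - u**2, 0.0))
    shape = f.shape[:-1]
    geom = np.zeros(shape + (4, 3))
    geom[..., 3, 1] = length  # C4 above C1
    geom[..., 1, 0] = d  # C2
    geom[..., 1, 1] = u
    geom[..., 2, 0] = d  # C3 above C2
    geom[..., 2, 1] = length + u
    return geom


def make_branching_ensemble(
    n_traj: int = 40,
    branch_times=(35.0, 55.0),
    path_templates=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 80.0,
    dt: float = 0.5,
):
    """Synthetic branching trajectory ensemble with ground-truth channels.

    Trajectories follow smooth feature-space templates that bifurcate at
    the given times; each trajectory gets a constant Gaussian offset of
    standard deviation ``noise_sd`` per feature plus small uncorrelated
    frame-to-frame jitter (``noise_sd / 10``), and the feature paths are
    realized as planar four-atom Cartesian geometries.  Returns
    ``(TrajectoryEnsemble, truth_labels)`` where the label is the template
    index.
    """
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    if path_templates is None:
        templates = default_branch_templates(times, branch_times)
    else:
        templates = np.asarray(path_templates, dtype=float)
        if templates.ndim != 3 or templates.shape[2] != 3:
            raise ParameterError(
                "path_templates must have shape (n_paths, n_frames, 3)"
            )
        if templates.shape[1] != times.size:
            raise ParameterError(
                f"templates have {templates.shape[1]} frames but the time "
                f"grid has {times.size}"
            )
    n_paths = templates.shape[0]
    rng = np.random.default_rng(seed)
    labels = np.arange(n_traj) % n_paths
    feats = templates[labels]
    if noise_sd > 0:
        offsets = rng.normal(0.0, noise_sd, size=(n_traj, 1, 3))
        jitter = rng.normal(0.0, noise_sd / 10.0, size=feats.shape)
        feats = feats + offsets + jitter
    coords = features_to_geometry(feats)
    ensemble = TrajectoryEnsemble(
        coords=coords, times=times, atom_labels=["C", "C", "C", "C"]
    )
    return ensemble, labels
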