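"""Trajectory pipeline: XYZ I/O, features, PCA, per-frame clustering,
channel assembly, and the synthetic branching-ensemble generator."""

import numpy as np
import pytest

from donkey.exceptions import ParameterError, TrajectoryFormatError
from donkey.trajectory import (
    TrajectoryEnsemble,
    assemble_channels,
    cluster_frames,
    compute_features,
    default_branch_templates,
    features_to_geometry,
    make_branching_ensemble,
    read_trajectories,
    reduce_features,
    write_xyz,
)


def _random_rigid_transform(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(0, 5.0, 3)


class TestXYZ:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 2.0, (4, 5, 3))  # 4 frames, 5 atoms
        path = tmp_path / "traj.xyz"
        write_xyz(path, coords, ["C", "C", "C", "C", "H"])
        ens = read_trajectories([path], dt=0.5)
        assert ens.coords.shape == (1, 4, 5, 3)
        np.testing.assert_allclose(ens.coords[0], coords, atol=1e-5)

    def test_ensemble_shape_from_multiple_files(self, tmp_path):
        rng = np.random.default_rng(1)
        paths = []
        for t in range(3):
            p = tmp_path / f"t{t}.xyz"
            write_xyz(p, rng.normal(size=(2, 4, 3)), ["C"] * 4)
            paths.append(p)
        ens = read_trajectories(paths, dt=0.5)
        assert (ens.n_traj, ens.n_frames, ens.n_atoms) == (3, 2, 4)
        np.testing.assert_allclose(ens.times, [0.0, 0.5])

    def test_malformed_coordinate_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nC 0 0 0\nC 1 oops 0\nC 0 1 0\n")
        with pytest.raises(TrajectoryFormatError, match="line 4"):
            read_trajectories([p])

    def test_inconsistent_atom_counts_name_the_file(self, tmp_path):
        rng = np.random.default_rng(2)
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        write_xyz(p1, rng.normal(size=(2, 4, 3)), ["C"] * 4)
        write_xyz(p2, rng.normal(size=(2, 5, 3)), ["C"] * 5)
        with pytest.raises(TrajectoryFormatError, match="b.xyz"):
            read_trajectories([p1, p2])


class TestFeatures:
    def test_square_geometry_wing_separation(self):
        # R12 = R34 = 2.0 exactly
        geom = np.array(
            [[0, 0, 0], [2.0, 0, 0], [2.0, 1.5, 0], [0, 1.5, 0]], float
        )
        ens = TrajectoryEnsemble(
            coords=np.tile(geom, (1, 2, 1, 1)),
            times=np.array([0.0, 0.5]),
            atom_labels=["C"] * 4,
        )
        fs = compute_features(ens, atoms=(0, 1, 2, 3))
        assert fs.features[0, 0, 0] == pytest.approx(2.0)

    def test_symmetric_geometry_zero_rhombicity(self):
        geom = features_to_geometry(np.array([2.4, 0.0, 1.5]))
        ens = TrajectoryEnsemble(
            coords=np.tile(geom, (1, 2, 1, 1)),
            times=np.array([0.0, 0.5]),
            atom_labels=["C"] * 4,
        )
        fs = compute_features(ens)
        assert fs.features[0, 0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_gives_zero_rates(self):
        geom = features_to_geometry(np.array([2.4, 0.3, 1.5]))[None]
        n_frames = 8
        coords = np.concatenate(
            [geom + t * np.array([0.3, -0.1, 0.2]) for t in range(n_frames)]
        )[None]
        ens = TrajectoryEnsemble(
            coords=coords,
            times=0.5 * np.arange(n_frames),
            atom_labels=["C"] * 4,
        )
        fs = compute_features(ens)
        assert np.abs(np.diff(fs.features, axis=1)).max() < 1e-10
        assert np.abs(fs.rates).max() < 1e-10

    def test_features_invariant_under_rotation(self):
        rng = np.random.default_rng(5)
        feats = np.array([[2.4, 0.4, 1.5], [2.0, -0.2, 1.4]])
        coords = features_to_geometry(feats)[None]  # (1, 2, 4, 3)
        ens = TrajectoryEnsemble(
            coords=coords, times=np.array([0.0, 0.5]), atom_labels=["C"] * 4
        )
        base = compute_features(ens).features
        q, t = _random_rigid_transform(rng)
        ens2 = TrajectoryEnsemble(
            coords=coords @ q.T + t,
            times=np.array([0.0, 0.5]),
            atom_labels=["C"] * 4,
        )
        np.testing.assert_allclose(
            compute_features(ens2).features, base, atol=1e-10
        )

    def test_geometry_realization_round_trip(self):
        # the planar four-atom construction reproduces the requested
        # wing separation, signed rhombicity and wing length exactly
        feats = np.array(
            [[2.45, 0.0, 1.55], [2.1, 0.8, 1.6], [1.8, -0.5, 1.45]]
        )
        coords = features_to_geometry(feats)[:, None, :, :]
        ens = TrajectoryEnsemble(
            coords=np.repeat(coords, 2, axis=1),
            times=np.array([0.0, 0.5]),
            atom_labels=["C"] * 4,
        )
        np.testing.assert_allclose(
            compute_features(ens).features[:, 0, :], feats, atol=1e-10
        )

    def test_too_few_frames_rejected(self):
        ens = TrajectoryEnsemble(
            coords=np.zeros((1, 1, 4, 3)) + np.arange(4)[None, None, :, None],
            times=np.array([0.0]),
            atom_labels=["C"] * 4,
        )
        with pytest.raises(Exception):
            compute_features(ens)


class TestReduceFeatures:
    def test_exact_planar_rank(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(2, 6))
        coeffs = rng.normal(size=(50, 2))
        reduced = reduce_features(coeffs @ basis)
        assert reduced.shape == (50, 2)

    def test_isotropic_keeps_all_components(self):
        rng = np.random.default_rng(7)
        reduced = reduce_features(rng.normal(size=(500, 6)))
        assert reduced.shape[1] == 6

    def test_zero_variance_yields_single_zero_column(self):
        with pytest.warns(RuntimeWarning):
            reduced = reduce_features(np.ones((10, 6)))
        assert reduced.shape == (10, 1)
        assert (reduced == 0).all()

    def test_retained_variance_bound(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 6)) * np.array([5, 3, 1, 0.05, 0.04, 0.03])
        reduced = reduce_features(x)
        d = reduced.shape[1]
        total = np.var(x - x.mean(0), axis=0).sum()
        kept = np.var(reduced, axis=0).sum()
        assert kept / total >= 1.0 - (6 - d) * 0.01 - 1e-9


class TestBranchingEnsemble:
    def test_noise_free_matches_templates_exactly(self):
        ens, labels = make_branching_ensemble(n_traj=8, noise_sd=0.0, seed=0)
        series = compute_features(ens)
        templates = default_branch_templates(ens.times)
        for i, lab in enumerate(labels):
            np.testing.assert_allclose(
                series.features[i], templates[lab], atol=1e-8
            )

    def test_seed_determinism(self):
        e1, l1 = make_branching_ensemble(n_traj=6, noise_sd=0.05, seed=3)
        e2, l2 = make_branching_ensemble(n_traj=6, noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(e1.coords, e2.coords)
        np.testing.assert_array_equal(l1, l2)

    def test_mismatched_template_grid_rejected(self):
        with pytest.raises(ParameterError):
            make_branching_ensemble(
                n_traj=4, path_templates=np.zeros((2, 7, 3)), seed=0
            )


class TestPerFrameClustering:
    def test_identical_trajectories_one_cluster_everywhere(self):
        ens, _ = make_branching_ensemble(n_traj=5, noise_sd=0.0, seed=0)
        ens.coords[:] = ens.coords[:1]  # clone one trajectory
        series = compute_features(ens)
        frames = cluster_frames(series, frame_interval=10.0)
        for t, lab in frames.items():
            assert (np.asarray(lab) == 0).all()

    def test_two_branch_fixture_splits_at_branch_time(self):
        # two paths exactly identical before t=35 fs, separating after
        times = np.arange(0.0, 80.25, 0.5)
        rise = np.where(
            times > 35.0,
            0.5 * (1 - np.cos(np.pi * np.minimum((times - 35.0) / 10.0, 1.0))),
            0.0,
        )
        base = np.stack(
            [2.45 + 0.0 * times, 0.0 * times, 1.55 + 0.0 * times], axis=-1
        )
        branch = base.copy()
        branch[:, 0] -= 0.8 * rise
        ens, labels = make_branching_ensemble(
            n_traj=16, path_templates=np.stack([base, branch]),
            noise_sd=0.0, seed=2,
        )
        series = compute_features(ens)
        frames = cluster_frames(series, frame_interval=5.0)
        # strictly before the branch (the central-difference rate at the
        # branch frame itself already sees the step)
        for t in (5.0, 15.0, 25.0, 30.0):
            assert np.max(frames[t]) == 0
        late = np.asarray(frames[70.0])
        assert np.max(late) == 1  # exactly two clusters after it
        assert len(set(zip(labels, late))) == 2

    def test_trajectory_permutation_equivariance(self):
        ens, _ = make_branching_ensemble(n_traj=12, noise_sd=0.01, seed=4)
        series = compute_features(ens)
        frames = cluster_frames(series, frame_interval=20.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        ens2 = TrajectoryEnsemble(
            coords=ens.coords[perm], times=ens.times, atom_labels=ens.atom_labels
        )
        frames2 = cluster_frames(
            compute_features(ens2), frame_interval=20.0
        )
        for t in frames:
            a = np.asarray(frames[t])[perm]
            b = np.asarray(frames2[t])
            # same partition up to label names
            assert len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestChannels:
    def test_uniform_labels_single_channel(self):
        per_frame = {40.0: [0, 0, 0], 50.0: [0, 0, 0], 70.0: [0, 0, 0]}
        ch = assemble_channels(per_frame, [40.0, 50.0, 70.0])
        assert ch.n_channels == 1
        assert ch.member_counts() == [3]

    def test_missing_checkpoint_rejected(self):
        with pytest.raises(ParameterError):
            assemble_channels({40.0: [0, 0]}, [40.0, 50.0])

    def test_four_paths_recovered_as_four_channels(self):
        ens, labels = make_branching_ensemble(
            n_traj=24, noise_sd=0.01, seed=5
        )
        series = compute_features(ens)
        frames = cluster_frames(series, frame_interval=5.0)
        ch = assemble_channels(frames, [40.0, 50.0, 70.0])
        assert ch.n_channels == 4
        # channels coincide with the generating path labels
        chan = ch.channel_labels()
        assert len(set(zip(labels, chan))) == 4

    def test_time_shifted_paths_form_distinct_channels(self):
        # two spatially identical paths, one delayed past a checkpoint
        times = np.arange(0.0, 80.25, 0.5)

        def ramp(center):
            return 0.5 * (1 + np.tanh((times - center) / 3.0))

        early = np.stack(
            [2.45 - 0.8 * ramp(30.0), 0.0 * times, 1.55 + 0.0 * times], axis=-1
        )
        late = np.stack(
            [2.45 - 0.8 * ramp(50.0), 0.0 * times, 1.55 + 0.0 * times], axis=-1
        )
        ens, labels = make_branching_ensemble(
            n_traj=16,
            path_templates=np.stack([early, late]),
            noise_sd=0.01,
            seed=6,
        )
        series = compute_features(ens)
        frames = cluster_frames(series, frame_interval=5.0)
        ch = assemble_channels(frames, [40.0])
        assert ch.n_channels == 2
        chan = ch.channel_labels()
        assert len(set(zip(labels, chan))) == 2
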