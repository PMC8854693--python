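"""Superposition, RMSD series, window splitting, selections, and I/O."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allosnet.core import (DegenerateGeometryError, StructuralError,
                           TrajectoryWindow, align_frames, parse_selection,
                           read_pdb, read_xyz, rmsd, rmsd_series,
                           split_windows, superpose, write_pdb, write_xyz)
from allosnet.synthetic import planted_binder, build_system, \
    sample_gaussian_trajectory

from conftest import make_bead_system


def brute_force_superpose_rmsd(mobile, reference):
    """Independent oracle: numerically minimise RMSD over rotation vector
    (translation handled by centering), no Kabsch algebra involved."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def loss(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((m @ rot.T - r) ** 2, axis=1)))

    best = min(
        (minimize(loss, x0, method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
         for x0 in [np.zeros(3), np.array([3.0, 0, 0]),
                    np.array([0, 3.0, 0]), np.array([0, 0, 3.0]),
                    np.array([1.5, 1.5, 1.5])]),
        key=lambda res: res.fun)
    return best.fun


class TestSuperpose:
    def test_identity(self, ten_atom_cloud):
        res = superpose(ten_atom_cloud, ten_atom_cloud)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-9)

    def test_rigid_motion_exactly_removed(self, ten_atom_cloud):
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ten_atom_cloud @ rot90.T + np.array([5.0, 0.0, 0.0])
        res = superpose(mobile, ten_atom_cloud)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.transform(mobile), ten_atom_cloud,
                                   atol=1e-9)

    def test_rotation_is_proper(self, rng):
        # near-planar clouds are where reflections sneak in
        pts = rng.standard_normal((8, 3))
        pts[:, 2] *= 0.01
        mob = pts[::-1] + rng.standard_normal(pts.shape)
        res = superpose(mob, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_cloud_matches_brute_force_oracle(self, rng,
                                                    ten_atom_cloud):
        rot = Rotation.from_euler("xyz", [20, -40, 65],
                                  degrees=True).as_matrix()
        mobile = ten_atom_cloud @ rot.T + np.array([1.0, -2.0, 3.0]) \
            + 0.5 * rng.standard_normal(ten_atom_cloud.shape)
        res = superpose(mobile, ten_atom_cloud)
        oracle = brute_force_superpose_rmsd(mobile, ten_atom_cloud)
        assert res.rmsd == pytest.approx(oracle, abs=1e-6)
        # least-squares: no rigid transform does better
        assert res.rmsd <= oracle + 1e-9

    def test_rmsd_invariant_under_common_rigid_transform(self, rng,
                                                         ten_atom_cloud):
        mobile = ten_atom_cloud + 0.3 * rng.standard_normal(
            ten_atom_cloud.shape)
        base = superpose(mobile, ten_atom_cloud).rmsd
        common = Rotation.from_euler("y", 123, degrees=True).as_matrix()
        shift = np.array([-3.0, 7.0, 0.5])
        moved = superpose(mobile @ common.T + shift,
                          ten_atom_cloud @ common.T + shift).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_selection_size_mismatch_rejected(self, ten_atom_cloud):
        with pytest.raises(StructuralError):
            superpose(ten_atom_cloud[:5], ten_atom_cloud)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line + 1.0)

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(pts, pts)


class TestSplitWindows:
    def test_twenty_windows_from_ten_replicas(self):
        # ten replicas × 1000 frames, two windows each → 20 of 500
        all_windows = []
        wid = 0
        for rep in range(10):
            frames = np.zeros((1000, 4, 3))
            ws = split_windows(frames, 2, replica_id=rep,
                               first_window_id=wid)
            wid += len(ws)
            all_windows.extend(ws)
        assert len(all_windows) == 20
        assert all(w.n_frames == 500 for w in all_windows)
        assert [w.window_id for w in all_windows] == list(range(20))

    def test_identity_partition(self):
        frames = np.arange(10 * 2 * 3, dtype=float).reshape(10, 2, 3)
        (w,) = split_windows(frames, 1)
        np.testing.assert_array_equal(w.coords, frames)

    def test_remainder_dropped_with_warning(self, caplog):
        frames = np.arange(11 * 1 * 3, dtype=float).reshape(11, 1, 3)
        with caplog.at_level("WARNING", logger="allosnet"):
            ws = split_windows(frames, 2)
        assert [w.n_frames for w in ws] == [5, 5]
        np.testing.assert_array_equal(ws[1].coords, frames[5:10])
        assert any("dropping" in r.message for r in caplog.records)

    def test_windows_are_contiguous_partition(self, rng):
        frames = rng.standard_normal((12, 3, 3))
        ws = split_windows(frames, 3)
        np.testing.assert_array_equal(
            np.concatenate([w.coords for w in ws]), frames)

    def test_bad_window_count_rejected(self):
        with pytest.raises(ValueError):
            split_windows(np.zeros((10, 1, 3)), 0)


class TestRmsdSeries:
    def _window(self, frames):
        return TrajectoryWindow(replica_id=0, window_id=0,
                                coords=np.asarray(frames))

    def test_reference_copies_give_zero(self, ten_atom_cloud):
        w = self._window([ten_atom_cloud] * 4)
        series = rmsd_series(w, ten_atom_cloud, np.arange(10), np.arange(10))
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_rigidly_displaced_measure_region(self, ten_atom_cloud):
        # fit region matches exactly; measure region shifted by 3 Å
        ref = np.vstack([ten_atom_cloud, ten_atom_cloud + 20.0])
        frame = ref.copy()
        frame[10:] += np.array([0.0, 3.0, 0.0])
        w = self._window([frame, frame])
        series = rmsd_series(w, ref, np.arange(10), np.arange(10, 20))
        np.testing.assert_allclose(series, 3.0, atol=1e-9)

    def test_matches_per_frame_oracle(self, rng, ten_atom_cloud):
        ref = np.vstack([ten_atom_cloud, 5 * rng.standard_normal((6, 3))])
        frames = ref[None] + 0.4 * rng.standard_normal((5, 16, 3))
        fit, mea = np.arange(10), np.arange(10, 16)
        w = self._window(frames)
        series = rmsd_series(w, ref, fit, mea)
        for f in range(5):
            res = superpose(frames[f], ref, fit)
            expected = rmsd(res.transform(frames[f][mea]), ref[mea])
            assert series[f] == pytest.approx(expected, abs=1e-12)
        assert np.all(series >= 0.0)


class TestSelections:
    def test_range_expression(self):
        system = build_system(planted_binder("localized_strong"))
        # receptor chain R residues 1-10 are the R1 lobe (nodes 0-9)
        assert parse_selection("R:1-10", system) == list(range(10))
        assert parse_selection("R:1-3,5", system) == [0, 1, 2, 4]
        assert parse_selection("P", system) == list(range(24, 36))

    def test_unknown_residue_rejected(self):
        system = build_system(planted_binder("localized_strong"))
        with pytest.raises(KeyError):
            parse_selection("R:999", system)


class TestIO:
    def test_pdb_round_trip_preserves_topology_and_coords(self, tmp_path):
        spec = planted_binder("localized_strong", n_replicas=1,
                              frames_per_replica=3)
        system, replicas, _ = sample_gaussian_trajectory(spec)
        path = tmp_path / "traj.pdb"
        write_pdb(system, replicas[0], path)
        system2, frames2 = read_pdb(path)
        assert frames2.shape == replicas[0].shape
        # PDB stores 3 decimals → 1e-3 Å round-trip accuracy
        np.testing.assert_allclose(frames2, replicas[0], atol=1.5e-3)
        assert [r.chain_id for r in system2.residues] == \
            [r.chain_id for r in system.residues]
        assert [r.res_id for r in system2.residues] == \
            [r.res_id for r in system.residues]
        assert [a.name for a in system2.atoms] == \
            [a.name for a in system.atoms]
        assert all(a.is_heavy for a in system2.atoms)

    def test_xyz_round_trip(self, tmp_path, rng):
        frames = rng.standard_normal((4, 6, 3)) * 10
        path = tmp_path / "traj.xyz"
        write_xyz(["C"] * 6, frames, path)
        elements, frames2 = read_xyz(path)
        assert elements == ["C"] * 6
        np.testing.assert_allclose(frames2, frames, atol=1e-5)

    def test_dcd_round_trip_through_mdanalysis(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        from allosnet.core import read_dcd
        spec = planted_binder("localized_strong", n_replicas=1,
                              frames_per_replica=4)
        system, replicas, _ = sample_gaussian_trajectory(spec)
        topo = tmp_path / "topo.pdb"
        write_pdb(system, replicas[0][:1], topo)
        dcd = tmp_path / "traj.dcd"
        u = mda.Universe(str(topo))
        with mda.Writer(str(dcd), n_atoms=system.n_atoms) as w:
            for frame in replicas[0]:
                u.atoms.positions = frame
                w.write(u.atoms)
        system2, frames = read_dcd(topo, dcd)
        assert system2.n_atoms == system.n_atoms
        assert frames.shape == replicas[0].shape
        # DCD stores float32 coordinates
        np.testing.assert_allclose(frames, replicas[0], atol=1e-3)

    def test_align_frames_removes_rigid_motion(self, rng, ten_atom_cloud):
        rots = Rotation.random(3, random_state=7).as_matrix()
        frames = np.stack([ten_atom_cloud @ r.T + i for i, r in
                           enumerate(rots)])
        aligned = align_frames(frames, ten_atom_cloud, np.arange(10))
        for fr in aligned:
            np.testing.assert_allclose(fr, ten_atom_cloud, atol=1e-9)
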