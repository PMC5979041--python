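"""Geometric featurization: pocket definition, contacts, centroid distances,
superposition RMSD, bound-state labelling and transition-path segments."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import bindkin.features as bf
from bindkin import io as bio


def _structure_from_xyz(xyz_nm, het_mask=None, element="C"):
    n = len(xyz_nm)
    het = np.zeros(n, bool) if het_mask is None else np.asarray(het_mask, bool)
    return bio.StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(["CA"] * n),
        element=np.array([element] * n),
        res_name=np.where(het, "LIG", "ALA"),
        res_seq=np.arange(1, n + 1),
        chain=np.array(["A"] * n),
        xyz=np.asarray(xyz_nm, float),
        is_het=het,
    )


class TestDefinePocket:
    def test_inclusive_threshold(self):
        xyz = [[0.3, 0, 0], [0.49, 0, 0], [0.51, 0, 0], [0, 0, 0]]
        s = _structure_from_xyz(xyz, het_mask=[False, False, False, True])
        pocket = bf.define_pocket(s, ligand_selection=[3], cutoff=0.5)
        assert set(pocket) == {0, 1}

    def test_boundary_distance_is_included(self):
        xyz = [[0.5, 0, 0], [0, 0, 0]]
        s = _structure_from_xyz(xyz, het_mask=[False, True])
        assert set(bf.define_pocket(s, [1], cutoff=0.5)) == {0}

    def test_zero_cutoff_keeps_only_coincident(self):
        xyz = [[0, 0, 0], [0.1, 0, 0], [0, 0, 0]]
        s = _structure_from_xyz(xyz, het_mask=[False, False, True])
        assert set(bf.define_pocket(s, [2], cutoff=0.0)) == {0}

    def test_matches_brute_force_on_toy_holo(self, toy_pdb_text):
        s = bio.read_structure(toy_pdb_text)
        lig = s.ligand_heavy_indices()
        pocket = bf.define_pocket(s, lig, cutoff=1.2)
        prot = s.protein_heavy_indices()
        expected = {int(i) for i in prot
                    if min(np.linalg.norm(s.xyz[i] - s.xyz[j]) for j in lig) <= 1.2}
        assert set(pocket) == expected

    def test_empty_pocket_warns(self):
        s = _structure_from_xyz([[0, 0, 0], [9, 9, 9]], het_mask=[False, True])
        with pytest.warns(UserWarning, match="empty"):
            pocket = bf.define_pocket(s, [1], cutoff=0.1)
        assert pocket.size == 0


class TestContactFeatures:
    def _traj(self, frames_xyz, structure):
        return bio.CoordinateTrajectory(np.asarray(frames_xyz, float), 1.0, structure)

    def test_single_frame_thresholds(self):
        s = _structure_from_xyz([[0, 0, 0], [0, 0, 0]], het_mask=[False, True])
        for d, expected in [(0.4, 1.0), (0.6, 0.0)]:
            traj = self._traj([[[d, 0, 0], [0, 0, 0]]], s)
            ft = bf.contact_features(traj, ligand_atoms=[1],
                                     residue_groups={"ALA1": [0]}, cutoff=0.5)
            assert ft.values[0, 0] == expected

    def test_empty_residue_group_rejected(self):
        s = _structure_from_xyz([[0, 0, 0], [0, 0, 0]], het_mask=[False, True])
        traj = self._traj([[[0, 0, 0], [0, 0, 0]]], s)
        with pytest.raises(ValueError, match="GLY9"):
            bf.contact_features(traj, [1], {"GLY9": []})

    def test_matches_brute_force_over_random_trajectory(self):
        rng = np.random.default_rng(0)
        n_at = 8
        s = _structure_from_xyz(np.zeros((n_at, 3)),
                                het_mask=[False] * 6 + [True] * 2)
        frames = rng.uniform(0, 1.2, size=(100, n_at, 3))
        traj = self._traj(frames, s)
        groups = {"R1": [0, 1, 2], "R2": [3, 4, 5]}
        ft = bf.contact_features(traj, [6, 7], groups, cutoff=0.5)
        for f in range(100):
            for j, grp in enumerate(groups.values()):
                dmin = cdist(frames[f, grp], frames[f, [6, 7]]).min()
                assert ft.values[f, j] == (1.0 if dmin <= 0.5 else 0.0)


class TestPocketLigandDistance:
    def test_identical_selections_give_zero(self):
        s = _structure_from_xyz([[1, 2, 3]])
        traj = bio.CoordinateTrajectory(np.tile([[1, 2, 3]], (5, 1, 1)), 1.0, s)
        d = bf.pocket_ligand_distance(traj, [0], [0])
        assert np.allclose(d, 0.0)

    def test_centroid_symmetry(self):
        s = _structure_from_xyz([[0, 0, 0], [1, 0, 0], [0.5, 0, 0]], element="H")
        traj = bio.CoordinateTrajectory(s.xyz[None], 1.0, s)
        d = bf.pocket_ligand_distance(traj, [0, 1], [2])
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_centroid_computation(self, toy_pdb_text):
        s = bio.read_structure(toy_pdb_text)
        rng = np.random.default_rng(1)
        frames = s.xyz[None] + rng.normal(0, 0.05, size=(7, s.n_atoms, 3))
        traj = bio.CoordinateTrajectory(frames, 0.5, s)
        pocket = s.protein_heavy_indices()
        lig = s.ligand_heavy_indices()
        d = bf.pocket_ligand_distance(traj, pocket, lig)
        m = s.masses()
        for f in range(7):
            cp = np.average(frames[f, pocket], axis=0, weights=m[pocket])
            cl = np.average(frames[f, lig], axis=0, weights=m[lig])
            assert d[f] == pytest.approx(np.linalg.norm(cp - cl), abs=1e-12)


class TestSuperposeRMSD:
    def _ref(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        return _structure_from_xyz(xyz)

    def test_identity_gives_zero(self):
        ref = self._ref()
        traj = bio.CoordinateTrajectory(ref.xyz[None], 1.0, ref)
        assert bf.superpose_rmsd(traj, ref, [0, 1, 2, 3])[0] == pytest.approx(0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        ref = self._ref()
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-3, 3, 3)
            frames.append(ref.xyz @ R.T + t)
        traj = bio.CoordinateTrajectory(np.stack(frames), 1.0, ref)
        rmsd = bf.superpose_rmsd(traj, ref, [0, 1, 2, 3])
        # float64 floor: RMSD is a sqrt of an O(eps) residual, ~1e-8
        assert np.all(rmsd < 1e-7)

    def test_displaced_atom_matches_brute_force_rotation_scan(self):
        ref = self._ref()
        mobile = ref.xyz.copy()
        mobile[3] += [0.0, 0.0, 0.2]
        traj = bio.CoordinateTrajectory(mobile[None], 1.0, ref)
        rmsd = bf.superpose_rmsd(traj, ref, [0, 1, 2, 3])[0]
        # brute force: dense scan over rotations after centroid alignment
        a = ref.xyz - ref.xyz.mean(axis=0)
        b = mobile - mobile.mean(axis=0)
        best = np.inf
        grid = np.linspace(-0.3, 0.3, 41)
        for ax in grid:
            for ay in grid:
                for az in grid:
                    R = Rotation.from_euler("xyz", [ax, ay, az]).as_matrix()
                    best = min(best, np.sqrt(((a - b @ R.T) ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(best, abs=1e-3)  # grid oracle has O(h^2) slack
        assert rmsd <= best + 1e-12  # optimal superposition cannot be worse

    def test_collinear_selection_rejected(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        ref = _structure_from_xyz(xyz)
        traj = bio.CoordinateTrajectory(xyz[None], 1.0, ref)
        with pytest.raises(ValueError, match="collinear"):
            bf.superpose_rmsd(traj, ref, [0, 1, 2])


class TestBoundStateLabels:
    def test_exact_dwell_is_bound(self):
        n = 10  # 10 frames x 10 ns = dwell_min exactly
        labels, first = bf.bound_state_labels(
            np.full(n, 0.1), np.full(n, 0.1), frame_interval=10.0, dwell_min=100.0)
        assert labels[0]
        assert first == 0.0

    def test_one_frame_short_is_unbound(self):
        n = 9
        labels, first = bf.bound_state_labels(
            np.full(n, 0.1), np.full(n, 0.1), frame_interval=10.0, dwell_min=100.0)
        assert not labels.any()
        assert first is None

    def test_first_binding_time_of_enumerated_excursions(self):
        # excursions of 50, 100 and 400 ns at 10 ns frames; dwell_min = 100 ns
        ok = np.ones(100, bool)
        dist = np.full(100, 0.5)  # above dist_max -> unbound
        dist[0:5] = 0.1     # 50 ns
        dist[20:30] = 0.1   # 100 ns starting at 200 ns
        dist[50:90] = 0.1   # 400 ns
        rmsd = np.full(100, 0.1)
        labels, first = bf.bound_state_labels(rmsd, dist, frame_interval=10.0,
                                              dwell_min=100.0)
        assert first == pytest.approx(200.0)
        assert not labels[:20].any()

    def test_monotone_in_dwell_min(self):
        rng = np.random.default_rng(3)
        rmsd = rng.uniform(0, 1, 300)
        dist = rng.uniform(0, 0.4, 300)
        prev = None
        for dwell in [10.0, 30.0, 60.0, 120.0]:
            labels, _ = bf.bound_state_labels(rmsd, dist, frame_interval=10.0,
                                              dwell_min=dwell)
            if prev is not None:
                assert np.all(prev | ~labels)  # increasing dwell never adds frames
            prev = labels

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frame grid"):
            bf.bound_state_labels(np.zeros(5), np.zeros(6), frame_interval=1.0)


class TestTransitionPathSegments:
    def test_monotone_descent_counts_frames_between_crossings(self):
        x = np.linspace(1.0, 0.2, 11)
        # crossings: below 0.6 first at frame 6, below 0.38 first at frame 8
        segs = bf.transition_path_segments(x, frame_interval=1.0)
        below_06 = int(np.argmax(x < 0.6))
        below_038 = int(np.argmax(x <= 0.38))
        assert len(segs) == 1
        assert segs[0] == pytest.approx((below_038 - below_06) * 1.0)

    def test_spec_style_hand_count(self):
        # stays unbound through frame 2, crosses 0.6 at frame 3, 0.38 at frame 8
        x = np.array([1.0, 0.9, 0.8, 0.55, 0.5, 0.5, 0.45, 0.4, 0.3, 0.2])
        segs = bf.transition_path_segments(x, frame_interval=1.0)
        assert segs == [5.0]

    def test_never_bound_gives_empty_list(self):
        x = np.full(50, 0.5)
        assert bf.transition_path_segments(x, frame_interval=1.0) == []

    def test_incomplete_excursion_not_counted(self):
        x = np.array([1.0, 0.5, 0.7, 1.0,   # dip below 0.6, returns: no segment
                      0.9, 0.5, 0.45, 0.3])  # completed crossing
        segs = bf.transition_path_segments(x, frame_interval=1.0)
        assert len(segs) == 1
        assert segs[0] == pytest.approx(2.0)  # frames 5,6 between exit and entry

    def test_unbinding_direction_symmetric(self):
        x = np.array([0.2, 0.3, 0.45, 0.5, 0.55, 0.7])
        segs = bf.transition_path_segments(x, frame_interval=1.0,
                                           direction="unbinding")
        assert len(segs) == 1
        assert segs[0] == pytest.approx(3.0)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="bound_below"):
            bf.transition_path_segments(np.zeros(3), 1.0, bound_below=0.7,
                                        unbound_above=0.6)
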