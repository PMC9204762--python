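"""Featurizer correctness against brute-force geometric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdtraj as md
import softmsm as sm
from softmsm.featurize import detect_pi_stacks, ligand_min_distances


def build_chain(n_res, n_frames=2, seed=0, **kw):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-np.pi, np.pi, (n_frames, n_res))
    psi = rng.uniform(-np.pi, np.pi, (n_frames, n_res))
    return sm.build_peptide_coordinates(phi, psi, **kw)


def point_topology(groups):
    """Topology of named residues each holding explicit carbon atoms."""
    top = md.Topology()
    ch = top.add_chain()
    for res_name, n_atoms in groups:
        r = top.add_residue(res_name, ch)
        for i in range(n_atoms):
            top.add_atom(f"C{i + 1}", md.element.carbon, r)
    return top


class TestNNDistances:
    def test_42_residues_gives_780_features(self):
        ens = build_chain(42)
        feats = sm.nn_distance_features(ens, min_seq_sep=3)
        assert feats.n_features == 780

    def test_too_short_chain_gives_zero_features(self):
        ens = build_chain(3)
        with pytest.warns(UserWarning, match="empty"):
            feats = sm.nn_distance_features(ens, min_seq_sep=3)
        assert feats.n_features == 0

    def test_five_residue_pairs_and_brute_force_values(self):
        ens = build_chain(5, n_frames=3, seed=2)
        feats = sm.nn_distance_features(ens, min_seq_sep=3)
        assert feats.labels == [(1, 4), (1, 5), (2, 5)]
        t = ens.trajectories[0]
        res_atoms = [[a.index for a in r.atoms] for r in t.topology.residues]
        for col, (i, j) in enumerate([(0, 3), (0, 4), (1, 4)]):
            for f in range(t.n_frames):
                d = min(
                    np.linalg.norm(t.xyz[f, a] - t.xyz[f, b])
                    for a in res_atoms[i] for b in res_atoms[j])
                assert feats.arrays[0][f, col] == pytest.approx(d, abs=1e-6)

    @given(n=st.integers(4, 50), s=st.integers(1, 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pair_count_formula(self, n, s):
        pairs = sm.residue_pairs(n, s)
        expected = max(0, (n - s)) * max(0, (n - s) + 1) // 2
        assert len(pairs) == expected

    def test_rigid_motion_invariance(self):
        ens = build_chain(6, n_frames=1, seed=3)
        ref = sm.nn_distance_features(ens).arrays[0]
        t = ens.trajectories[0]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t.xyz = (t.xyz @ R.T + np.array([1.0, -2.0, 0.5])).astype(np.float32)
        moved = sm.nn_distance_features(ens).arrays[0]
        assert np.allclose(ref, moved, atol=1e-5)


class TestDihedrals:
    def test_terminal_angles_missing_and_counts(self):
        n = 8
        ens = build_chain(n)
        bb = sm.backbone_dihedrals(ens).stacked
        phi, psi = bb[:, :n], bb[:, n:]
        assert np.isnan(phi[:, 0]).all() and np.isfinite(phi[:, 1:]).all()
        assert np.isnan(psi[:, -1]).all() and np.isfinite(psi[:, :-1]).all()

    def test_chi1_absent_for_backbone_only_chain(self):
        ens = build_chain(5, residue_name="GLY", include_sidechain=False)
        with pytest.warns(UserWarning, match="chi1"):
            feats = sm.chi1_dihedrals(ens)
        assert feats.n_features == 0


class TestLigandDistances:
    def _two_point_system(self, lig_xyz, pep_xyz, box=None):
        top = point_topology([("ALA", len(pep_xyz[0])), ("LIG", len(lig_xyz[0]))])
        xyz = np.concatenate([pep_xyz, lig_xyz], axis=1).astype(np.float32)
        traj = md.Trajectory(xyz, top)
        if box is not None:
            traj.unitcell_lengths = np.tile(box, (len(xyz), 1)).astype(np.float32)
            traj.unitcell_angles = np.full((len(xyz), 3), 90.0, dtype=np.float32)
        return sm.TrajectoryEnsemble([traj], 250.0, ligand_resname="LIG")

    def test_single_atom_pair_is_euclidean(self):
        pep = np.zeros((1, 1, 3))
        lig = np.array([[[0.3, 0.4, 0.0]]])
        ens = self._two_point_system(lig, pep)
        d = ligand_min_distances(ens, "residue")
        assert d.arrays[0][0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(4)
        pep = rng.uniform(0, 1, (2, 15, 3))
        lig = rng.uniform(0, 1, (2, 10, 3))
        top = point_topology([("ALA", 3)] * 5 + [("LIG", 10)])
        xyz = np.concatenate([pep, lig], axis=1).astype(np.float32)
        ens = sm.TrajectoryEnsemble([md.Trajectory(xyz, top)], 250.0,
                                    ligand_resname="LIG")
        d = ligand_min_distances(ens, "residue")
        assert d.n_features == 5
        for f in range(2):
            for r in range(5):
                expected = min(
                    np.linalg.norm(pep[f, 3 * r + a] - lig[f, b])
                    for a in range(3) for b in range(10))
                assert d.arrays[0][f, r] == pytest.approx(expected, abs=1e-5)
        da = ligand_min_distances(ens, "atom")
        assert da.n_features == 10
        for b in range(10):
            expected = min(np.linalg.norm(pep[0, a] - lig[0, b]) for a in range(15))
            assert da.arrays[0][0, b] == pytest.approx(expected, abs=1e-5)

    def test_minimum_image_across_box_boundary(self):
        box = np.array([2.0, 2.0, 2.0])
        pep = np.array([[[0.1, 1.0, 1.0]]])
        lig = np.array([[[1.9, 1.0, 1.0]]])
        ens = self._two_point_system(lig, pep, box=box)
        d = ligand_min_distances(ens, "residue").arrays[0][0, 0]
        # explicit image enumeration oracle
        best = min(
            np.linalg.norm(pep[0, 0] - (lig[0, 0] + box * np.array([i, j, k])))
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1))
        assert d == pytest.approx(best, abs=1e-6)
        assert d == pytest.approx(0.2, abs=1e-6)

    def test_empty_ligand_selection_rejected(self):
        ens = build_chain(4)
        with pytest.raises(ValueError, match="ligand"):
            ligand_min_distances(ens, "residue")


class TestPiStacks:
    def _ring_system(self, centroids_a, centroids_b, n_atoms=6, radius=0.14):
        """Two rigid hexagonal rings whose centroids follow given tracks."""
        n_frames = len(centroids_a)
        ang = 2 * np.pi * np.arange(n_atoms) / n_atoms
        ring = radius * np.stack([np.cos(ang), np.sin(ang), np.zeros(n_atoms)], 1)
        xyz = np.empty((n_frames, 2 * n_atoms, 3), dtype=np.float32)
        xyz[:, :n_atoms] = centroids_a[:, None, :] + ring
        xyz[:, n_atoms:] = centroids_b[:, None, :] + ring
        top = point_topology([("LIG", n_atoms), ("PHE", n_atoms)])
        traj = md.Trajectory(xyz, top)
        ens = sm.TrajectoryEnsemble([traj], 250.0, ligand_resname="LIG")
        lig = {"lig": list(range(n_atoms))}
        res = {"PHE": list(range(n_atoms, 2 * n_atoms))}
        return ens, lig, res

    def test_stacked_and_far_rings(self):
        a = np.zeros((2, 3))
        b = np.array([[0.0, 0.0, 0.35], [0.0, 0.0, 2.0]])
        ens, lig, res = self._ring_system(a, b)
        s = detect_pi_stacks(ens, lig, res, centroid_cutoff=0.55)
        assert s.arrays[0][0, 0] and not s.arrays[0][1, 0]

    def test_scripted_centroids_match_threshold_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (40, 3))
        b = rng.uniform(0, 1, (40, 3))
        ens, lig, res = self._ring_system(a, b)
        s = detect_pi_stacks(ens, lig, res, centroid_cutoff=0.55)
        expected = np.linalg.norm(a - b, axis=1) <= 0.55
        assert (s.arrays[0][:, 0] == expected).all()

    def test_small_ring_rejected(self):
        a = np.zeros((1, 3))
        ens, lig, res = self._ring_system(a, a + 0.1, n_atoms=4)
        with pytest.raises(ValueError, match="at least 5"):
            detect_pi_stacks(ens, lig, res)
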