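"""Generator correctness: state chains, emissions, telegraph contacts, geometry."""

import numpy as np
import pytest
from scipy import integrate

import softmsm as sm
from softmsm.synthetic import telegraph_step_probs

from conftest import count_transition_matrix


def make_spec(**kw):
    base = dict(
        n_states=2,
        transition_matrix=np.array([[0.99, 0.01], [0.02, 0.98]]),
        dt_ps=250.0, n_trajectories=5, n_frames=500, n_residues=2,
        phi_means=np.radians([[-110.0], [-60.0]]),
        phi_kappas=8.0, psi_means=0.0, psi_kappas=8.0, seed=0,
    )
    base.update(kw)
    return sm.GroundTruthSpec(**base)


class TestStatePath:
    def test_identity_matrix_freezes_paths(self):
        spec = make_spec(transition_matrix=np.eye(2))
        for p in sm.simulate_state_path(spec):
            assert (p == p[0]).all()

    def test_empirical_transition_counts_match_matrix(self):
        T = np.array([[0.99, 0.01], [0.02, 0.98]])
        spec = make_spec(n_trajectories=200, n_frames=5000, seed=3)
        paths = sm.simulate_state_path(spec)
        emp = count_transition_matrix(paths, 2)
        counts = np.zeros(2)
        for p in paths:
            counts += np.bincount(p[:-1], minlength=2)
        for i in range(2):
            se = np.sqrt(T[i, 0] * (1 - T[i, 0]) / counts[i])
            assert abs(emp[i, 0] - T[i, 0]) < 3 * se

    def test_same_seed_bitwise_identical(self):
        spec = make_spec(seed=7)
        a = sm.simulate_state_path(spec)
        b = sm.simulate_state_path(spec)
        for x, y in zip(a, b):
            assert (x == y).all()

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            make_spec(transition_matrix=np.array([[0.9, 0.2], [0.02, 0.98]]))
        with pytest.raises(ValueError, match="non-negative"):
            make_spec(transition_matrix=np.array([[1.1, -0.1], [0.02, 0.98]]))


class TestDihedralEmission:
    def test_infinite_concentration_is_degenerate(self):
        paths = [np.zeros(100, dtype=int)]
        out = sm.emit_dihedral_series(paths, np.array([[1.0]]),
                                      np.array([[np.inf]]), seed=0)
        assert np.allclose(out[0], 1.0)

    def test_circular_mean_recovered(self):
        mu, kappa, n = 2.0, 4.0, 100_000
        paths = [np.zeros(n, dtype=int)]
        out = sm.emit_dihedral_series(paths, np.array([[mu]]),
                                      np.array([[kappa]]), seed=1)
        z = np.exp(1j * out[0][:, 0]).mean()
        # circular-mean standard error ~ 1/sqrt(n * kappa) at high kappa
        assert abs(np.angle(z) - mu) < 3.0 / np.sqrt(n * kappa)

    def test_state_identification_error_matches_overlap(self):
        mu = np.array([[-1.5], [1.5]])
        kappa = np.full((2, 1), 4.0)
        n = 50_000
        paths = [np.tile([0, 1], n // 2)]
        out = sm.emit_dihedral_series(paths, mu, kappa, seed=2)[0][:, 0]
        # nearest-mean classification on the circle
        d0 = np.abs(np.angle(np.exp(1j * (out - mu[0, 0]))))
        d1 = np.abs(np.angle(np.exp(1j * (out - mu[1, 0]))))
        pred = (d1 < d0).astype(int)
        err = (pred != paths[0]).mean()
        # numeric overlap: P(vonMises(mu0) falls nearer mu1)
        from scipy.stats import vonmises
        grid = np.linspace(-np.pi, np.pi, 20001)
        pdf0 = vonmises.pdf(grid, kappa[0, 0], loc=mu[0, 0])
        nearer1 = np.abs(np.angle(np.exp(1j * (grid - mu[1, 0])))) < \
            np.abs(np.angle(np.exp(1j * (grid - mu[0, 0]))))
        p_err = integrate.trapezoid(pdf0 * nearer1, grid)
        se = np.sqrt(p_err * (1 - p_err) / n)
        assert abs(err - p_err) < 3 * se

    def test_missing_state_parameters_rejected(self):
        paths = [np.array([0, 1, 2])]
        with pytest.raises(ValueError, match="no emission parameters"):
            sm.emit_dihedral_series(paths, np.zeros((2, 1)), np.ones((2, 1)), 0)


class TestTelegraph:
    def test_absorbing_on_state(self):
        s = sm.emit_telegraph_contacts({"c": (0.1, 0.0)}, 500, 250.0, seed=0,
                                       initial={"c": True})
        assert s.stacked.all()

    @pytest.mark.parametrize("kon,koff,target", [
        (0.05, 0.05, 0.5),
        (0.01, 0.05, 1.0 / 6.0),
    ])
    def test_stationary_on_fraction(self, kon, koff, target):
        n = 200_000
        s = sm.emit_telegraph_contacts({"c": (kon, koff)}, n, 250.0, seed=4)
        frac = s.stacked.mean()
        # autocorrelation-corrected standard error of the on-fraction
        relax = np.exp(-(kon + koff) * 0.25)
        n_eff = n * (1 - relax) / (1 + relax)
        se = np.sqrt(target * (1 - target) / n_eff)
        assert abs(frac - target) < 3 * se

    def test_exact_step_probabilities(self):
        p_off_on, p_on_on = telegraph_step_probs(0.05, 0.05, 1e9)
        assert p_off_on == pytest.approx(0.5)  # fully relaxed
        assert p_on_on == pytest.approx(0.5)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sm.emit_telegraph_contacts({"c": (-0.1, 0.05)}, 10, 250.0, seed=0)


class TestChainConstruction:
    def test_bond_lengths_are_ideal(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-np.pi, np.pi, (3, 5))
        psi = rng.uniform(-np.pi, np.pi, (3, 5))
        ens = sm.build_peptide_coordinates(phi, psi)
        t = ens.trajectories[0]
        names = {}
        for a in t.topology.atoms:
            names[(a.residue.index, a.name)] = a.index
        xyz = t.xyz
        for i in range(5):
            d = np.linalg.norm(xyz[:, names[(i, "N")]] - xyz[:, names[(i, "CA")]],
                               axis=1)
            assert np.allclose(d, 0.1458, atol=1e-6)
            d = np.linalg.norm(xyz[:, names[(i, "CA")]] - xyz[:, names[(i, "C")]],
                               axis=1)
            assert np.allclose(d, 0.1525, atol=1e-6)
            if i:
                d = np.linalg.norm(xyz[:, names[(i - 1, "C")]] - xyz[:, names[(i, "N")]],
                                   axis=1)
                assert np.allclose(d, 0.1329, atol=1e-6)

    def test_dihedral_round_trip(self):
        rng = np.random.default_rng(5)
        phi = rng.uniform(-np.pi, np.pi, (4, 6))
        psi = rng.uniform(-np.pi, np.pi, (4, 6))
        chi1 = rng.uniform(-np.pi, np.pi, (4, 6))
        ens = sm.build_peptide_coordinates(phi, psi, chi1)
        bb = sm.backbone_dihedrals(ens).stacked
        rec_phi, rec_psi = bb[:, :6], bb[:, 6:]
        assert np.nanmax(np.abs(np.angle(np.exp(1j * (rec_phi[:, 1:] - phi[:, 1:]))))) < 1e-6
        assert np.nanmax(np.abs(np.angle(np.exp(1j * (rec_psi[:, :-1] - psi[:, :-1]))))) < 1e-6
        rec_chi = sm.chi1_dihedrals(ens).stacked
        assert np.max(np.abs(np.angle(np.exp(1j * (rec_chi - chi1))))) < 1e-6

    def test_atom_count(self):
        phi = np.zeros((1, 7))
        psi = np.zeros((1, 7))
        ens = sm.build_peptide_coordinates(phi, psi)
        assert ens.trajectories[0].n_atoms == 7 * 5

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sm.build_peptide_coordinates(np.zeros((1, 2)), np.zeros((1, 2)))


class TestBenchmark:
    def test_smoke_contract(self, tmp_path, small_spec):
        spec = sm.default_benchmark_spec(0, n_trajectories=3, n_frames=100)
        bench = sm.make_benchmark_ensemble(spec, out_dir=tmp_path)
        phi = sm.FeatureSeries.from_csv(tmp_path / "phi.csv")
        assert phi.n_frames == 300
        con = sm.ContactSeries.from_csv(tmp_path / "contacts.csv")
        assert con.n_features == len(spec.contact_rates)
        assert (tmp_path / "ground_truth.json").exists()

    def test_true_timescale_matches_eigenvalue(self, small_spec, small_benchmark):
        lam2 = np.sort(np.linalg.eigvals(small_spec.transition_matrix))[0]
        expected = -small_spec.dt_ns / np.log(lam2)
        assert small_benchmark.ground_truth.true_timescales_ns[0] == \
            pytest.approx(expected, rel=1e-12)

    def test_seed_isolation(self):
        a = sm.make_benchmark_ensemble(
            sm.default_benchmark_spec(1, n_trajectories=2, n_frames=50))
        b = sm.make_benchmark_ensemble(
            sm.default_benchmark_spec(2, n_trajectories=2, n_frames=50))
        assert not all((x == y).all() for x, y in
                       zip(a.ground_truth.state_paths, b.ground_truth.state_paths))
        assert np.allclose(a.ground_truth.true_timescales_ns,
                           b.ground_truth.true_timescales_ns)
        assert np.allclose(a.ground_truth.true_populations,
                           b.ground_truth.true_populations)

    def test_coordinate_benchmark_readable(self):
        spec = sm.default_benchmark_spec(0, n_trajectories=2, n_frames=20)
        bench = sm.make_benchmark_ensemble(spec, coordinates=True)
        feats = sm.nn_distance_features(bench.ensemble)
        assert feats.n_frames == 40
        assert feats.n_features == len(sm.residue_pairs(spec.n_residues, 3))
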