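import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinelastic import enm

TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   4       3.800   3.800   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       3.800   3.800   0.000  1.00  0.00           C
END
"""


def tetrahedron() -> enm.CaStructure:
    pos = 0.38 * np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0],
         [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]
    )
    ids = [("A", i + 1, "ALA") for i in range(4)]
    return enm.CaStructure(pos, ids)


class TestReadCaStructure:
    def test_toy_pdb_order_and_gaps(self):
        st_ = enm.read_ca_structure(TOY_PDB)
        assert st_.N == 3
        assert [r[1] for r in st_.residue_ids] == [1, 2, 4]
        assert st_.gaps == [("A", 3)]  # residue 3 missing, never interpolated
        # PDB Å → nm
        assert st_.positions[1, 0] == pytest.approx(0.38)

    def test_altloc_resolved_by_occupancy(self):
        st_ = enm.read_ca_structure(ALTLOC_PDB)
        assert st_.N == 3
        assert st_.positions[0, 0] == pytest.approx(0.9)  # occupancy 0.60 wins

    def test_no_ca_atoms_is_format_error(self):
        with pytest.raises(enm.PDBFormatError):
            enm.read_ca_structure("ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\nEND\n")


class TestBuildNetwork:
    def test_spring_constant_at_decay_length(self):
        st_ = enm.CaStructure(
            np.array([[0, 0, 0], [0.3, 0, 0], [10, 10, 10.0]]),
            [("A", i, "ALA") for i in range(3)],
        )
        net = enm.build_network(st_, C=100.0, r0=0.3)
        pair01 = np.where((net.pairs == [0, 1]).all(axis=1))[0][0]
        assert net.pair_constants[pair01] == pytest.approx(100.0 * np.exp(-1.0))

    def test_direct_evaluation(self):
        # k = C exp(-r²/r0²) at C=47.4, r=0.5, r0=0.3
        st_ = enm.CaStructure(
            np.array([[0, 0, 0], [0.5, 0, 0], [0.25, 0.43, 0.0]]),
            [("A", i, "ALA") for i in range(3)],
        )
        net = enm.build_network(st_, C=47.4, r0=0.3)
        pair01 = np.where((net.pairs == [0, 1]).all(axis=1))[0][0]
        assert net.pair_constants[pair01] == pytest.approx(47.4 * np.exp(-25.0 / 9.0), rel=1e-12)
        assert net.pair_constants[pair01] == pytest.approx(2.95, abs=0.01)

    def test_duplicate_coordinates_rejected(self):
        st_ = enm.CaStructure(
            np.array([[0, 0, 0], [0, 0, 0], [0.38, 0, 0.0]]),
            [("A", i, "ALA") for i in range(3)],
        )
        with pytest.raises(ValueError, match="duplicate"):
            enm.build_network(st_)


def _finite_difference_hessian(structure, network, h=1e-6):
    """Independent oracle: FD Hessian of the pair-spring energy."""

    def energy(flat):
        X = flat.reshape(-1, 3)
        d = np.linalg.norm(X[network.pairs[:, 1]] - X[network.pairs[:, 0]], axis=1)
        return float(np.sum(0.5 * network.pair_constants * (d - network.reference_distances) ** 2))

    x0 = structure.positions.ravel()
    n = x0.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (4 * h * h)
    return H


class TestComputeModes:
    def test_eigenvalues_match_fd_oracle(self):
        st_ = tetrahedron()
        net = enm.build_network(st_, C=100.0, r0=0.5)
        modes = enm.compute_modes(net, st_, 6)
        H = _finite_difference_hessian(st_, net)
        ev = np.linalg.eigvalsh(H)
        assert np.allclose(modes.eigenvalues, ev[6:], rtol=1e-6)

    def test_mode_normalization(self, helix_modes):
        st_, _, modes = helix_modes
        for m in modes.modes:
            assert np.sum(m**2) == pytest.approx(st_.N * modes.normalization_f, rel=1e-8)

    def test_modes_orthogonal(self, helix_modes):
        _, _, modes = helix_modes
        flat = modes.modes.reshape(modes.n_modes, -1)
        G = flat @ flat.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).min()

    def test_avg_deformation_energy_equals_eigenvalue(self, helix_modes):
        # with f = 1 nm², summing the per-atom strain double-counts each pair,
        # so the atom-mean equals dᵀHd/N = λ — a strong cross-check of Eq-level algebra
        _, _, modes = helix_modes
        assert np.allclose(modes.avg_deformation_energy, modes.eigenvalues, rtol=1e-8)

    def test_disconnected_network_reported(self):
        pos = np.vstack([tetrahedron().positions, tetrahedron().positions + 50.0])
        st_ = enm.CaStructure(pos, [("A", i, "ALA") for i in range(8)])
        net = enm.build_network(st_, r0=0.5)
        with pytest.raises(enm.DisconnectedNetworkError, match="components"):
            enm.compute_modes(net, st_, 3)


class TestDeformationEnergy:
    def _pair_structure(self):
        st_ = enm.CaStructure(
            np.array([[0, 0, 0], [0.38, 0, 0], [50.0, 50, 50]]),
            [("A", i, "ALA") for i in range(3)],
        )
        net = enm.build_network(st_, C=100.0, r0=0.3)
        k01 = net.pair_constants[np.where((net.pairs == [0, 1]).all(axis=1))[0][0]]
        return st_, net, k01

    def test_perpendicular_displacement_costs_nothing(self):
        st_, net, _ = self._pair_structure()
        d = np.array([[0, 0.1, 0], [0, -0.1, 0], [0, 0, 0.0]])
        prof = enm.deformation_energy(st_, net, d)
        assert np.allclose(prof.per_atom_energy, 0.0, atol=1e-12)

    def test_along_bond_displacement(self):
        st_, net, k01 = self._pair_structure()
        delta = 0.05
        d = np.array([[delta, 0, 0], [0, 0, 0], [0, 0, 0.0]])
        prof = enm.deformation_energy(st_, net, d)
        assert prof.per_atom_energy[0] == pytest.approx(0.5 * k01 * delta**2, rel=1e-9)
        assert prof.per_atom_energy[1] == pytest.approx(0.5 * k01 * delta**2, rel=1e-9)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_rigid_fields_cost_nothing(self, seed):
        # translation + rotation of a random connected cloud: zero strain
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 50))
        pos = r.uniform(0, 1.5, (n, 3))
        st_ = enm.CaStructure(pos, [("A", i, "ALA") for i in range(n)])
        net = enm.build_network(st_, r0=2.0)
        T = r.normal(size=3)
        Om = r.normal(size=3)
        d = T + np.cross(Om, pos - pos.mean(axis=0))
        prof = enm.deformation_energy(st_, net, d)
        assert np.abs(prof.per_atom_energy).max() < 1e-8


class TestModeSelection:
    def _fake_modes(self, averages):
        n = len(averages)
        per_atom = np.tile(np.asarray(averages, dtype=float)[:, None], (1, 4))
        return enm.NormalModeSet(
            modes=np.zeros((n, 4, 3)),
            eigenvalues=np.asarray(averages, dtype=float),
            normalization_f=1.0,
            avg_deformation_energy=np.asarray(averages, dtype=float),
            per_atom_energy=per_atom,
        )

    def test_maximal_prefix_below_threshold(self):
        selected, _ = enm.mode_selection_report(self._fake_modes([390, 393, 417]), 400.0)
        assert selected == [0, 1]

    def test_all_above_threshold_warns_empty(self):
        with pytest.warns(UserWarning):
            selected, _ = enm.mode_selection_report(self._fake_modes([500, 600]), 400.0)
        assert selected == []

    def test_fraction_below_threshold_non_increasing(self, helix_modes):
        _, _, modes = helix_modes
        _, fractions = enm.mode_selection_report(modes, float(np.median(modes.avg_deformation_energy)))
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestPartitionCubes:
    def test_min_atoms_rule(self):
        pos = np.vstack([np.random.default_rng(0).uniform(0, 0.5, (5, 3)),
                         np.array([[5.0, 5, 5], [5.1, 5, 5]])])
        st_ = enm.CaStructure(pos, [("A", i, "ALA") for i in range(7)])
        prof = enm.DeformationProfile(np.zeros(7), (0,))
        cubes = enm.partition_cubes(st_, prof, cube_side=1.2, min_atoms=3, threshold=400.0)
        assert len(cubes) == 1
        assert len(cubes[0].atom_indices) == 5

    def test_threshold_is_strict(self):
        pos = np.random.default_rng(1).uniform(0, 0.5, (4, 3))
        st_ = enm.CaStructure(pos, [("A", i, "ALA") for i in range(4)])
        prof = enm.DeformationProfile(np.full(4, 400.0), (0,))
        with pytest.warns(UserWarning):
            assert enm.partition_cubes(st_, prof, threshold=400.0) == []

    def test_matches_bruteforce_binning(self, rng):
        pos = rng.uniform(0, 4.0, (100, 3))
        st_ = enm.CaStructure(pos, [("A", i, "ALA") for i in range(100)])
        prof = enm.DeformationProfile(rng.uniform(0, 800, 100), (0,))
        side, min_atoms, thr = 1.2, 3, 400.0
        cubes = enm.partition_cubes(st_, prof, side, min_atoms, thr)
        # independent oracle: dict-of-lists floor binning
        lo = pos.min(axis=0)
        expected: dict = {}
        for a in range(100):
            key = tuple(int(np.floor((pos[a, d] - lo[d]) / side)) for d in range(3))
            expected.setdefault(key, []).append(a)
        admitted = {
            k: v for k, v in expected.items()
            if len(v) >= min_atoms and np.mean(prof.per_atom_energy[v]) < thr
        }
        assert {c.cell for c in cubes} == set(admitted)
        for c in cubes:
            assert sorted(c.atom_indices) == sorted(admitted[c.cell])


class TestRigidBodyFit:
    def test_pure_translation(self, rng):
        pos = rng.uniform(0, 1, (6, 3))
        fit = enm.fit_rigid_body(pos, np.tile([1.0, 0, 0], (6, 1)))
        assert np.allclose(fit.T_vec, [1, 0, 0], atol=1e-12)
        assert np.allclose(fit.Omega, 0, atol=1e-12)
        assert fit.residual < 1e-20

    def test_pure_rotation(self, rng):
        pos = rng.uniform(0, 1, (8, 3))
        centered = pos - pos.mean(axis=0)
        omega = np.array([0.0, 0.0, 0.01])
        d = np.cross(omega, centered)
        fit = enm.fit_rigid_body(pos, d)
        assert np.allclose(fit.Omega, omega, atol=1e-12)
        assert np.allclose(fit.T_vec, 0, atol=1e-12)

    def test_noisy_rigid_matches_normal_equations_oracle(self, rng):
        pos = rng.uniform(0, 1, (10, 3))
        centered = pos - pos.mean(axis=0)
        T, Om = np.array([0.2, -0.1, 0.3]), np.array([0.05, 0.02, -0.04])
        sigma = 1e-3
        d = T + np.cross(Om, centered) + rng.normal(0, sigma, (10, 3))
        fit = enm.fit_rigid_body(pos, d)
        assert np.allclose(fit.T_vec, T, atol=3 * sigma)
        assert np.allclose(fit.Omega, Om, atol=3 * sigma)
        # dense normal-equations oracle
        A = np.zeros((30, 6))
        for i, r in enumerate(centered):
            A[3 * i:3 * i + 3, :3] = np.eye(3)
            A[3 * i:3 * i + 3, 3:] = -np.array(
                [[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]]
            )
        sol = np.linalg.solve(A.T @ A, A.T @ d.ravel())
        assert np.allclose(np.concatenate([fit.T_vec, fit.Omega]), sol, atol=1e-10)
        assert fit.residual == pytest.approx(float(np.sum((A @ sol - d.ravel()) ** 2)), rel=1e-8)

    def test_collinear_rejected(self):
        pos = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(enm.DegenerateGeometryError):
            enm.fit_rigid_body(pos, np.zeros((5, 3)))


class TestPairSimilarity:
    def _m(self, T, Om):
        return enm.RigidBodyMotion(np.asarray(T, float), np.asarray(Om, float), 0.0)

    def test_identical_motions_capped(self):
        a = self._m([1, 0, 0], [0, 1, 0])
        assert enm.pair_similarity(a, a) == pytest.approx(4 * enm.S_CAP)

    def test_opposite_motions_zero(self):
        a = self._m([1, 2, 3], [0.1, 0.2, 0.3])
        b = self._m([-1, -2, -3], [-0.1, -0.2, -0.3])
        assert enm.pair_similarity(a, b) == 0.0

    def test_orthogonal_unit_vectors(self):
        a = self._m([1, 0, 0], [1, 0, 0])
        b = self._m([0, 1, 0], [0, 1, 0])
        assert enm.pair_similarity(a, b) == pytest.approx(4.0)


class TestClusterDomains:
    def _cubes(self, n):
        return [
            enm.Cube(cell=(i, 0, 0), atom_indices=np.array([i]), mean_energy=0.0)
            for i in range(n)
        ]

    def test_two_blocks(self):
        S = np.array(
            [[0, 100, 1, 1], [100, 0, 1, 1], [1, 1, 0, 100], [1, 1, 100, 0.0]]
        )
        d = enm.cluster_domains(self._cubes(4), S, coarseness_c=10.0, n_atoms=4)
        assert d.n_domains == 2
        assert d.cube_labels[0] == d.cube_labels[1]
        assert d.cube_labels[2] == d.cube_labels[3]

    def test_coarseness_must_exceed_one(self):
        with pytest.raises(ValueError):
            enm.cluster_domains(self._cubes(2), np.zeros((2, 2)), 1.0, 2)

    def test_large_coarseness_single_domain(self, rng):
        n = 6
        S = rng.uniform(1, 50, (n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        d = enm.cluster_domains(self._cubes(n), S, coarseness_c=1e6, n_atoms=n)
        assert d.n_domains == 1

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_domain_count_non_increasing_in_coarseness(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 10))
        S = r.uniform(0, 100, (n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        cubes = self._cubes(n)
        counts = [
            enm.cluster_domains(cubes, S, c, n).n_domains
            for c in [1.01, 2, 5, 10, 100, 1e5]
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_off_domain_sentinel(self):
        cubes = [enm.Cube((0, 0, 0), np.array([0, 1]), 0.0)]
        with pytest.warns(UserWarning):
            d = enm.cluster_domains(cubes, np.zeros((1, 1)), 10.0, n_atoms=4)
        assert list(d.residue_labels) == [0, 0, enm.OFF_DOMAIN, enm.OFF_DOMAIN]


class TestDecomposeDomains:
    def test_helix_end_to_end(self, helix_modes):
        st_, net, modes = helix_modes
        thr = float(np.sum(modes.avg_deformation_energy)) * 10
        d = enm.decompose_domains(st_, net, modes, threshold=thr, coarseness_c=10.0)
        assert d.n_domains >= 1
        assert len(d.residue_labels) == st_.N
        labeled = d.residue_labels[d.residue_labels != enm.OFF_DOMAIN]
        assert labeled.size > 0
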