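"""FEM diffusion solver, system matrices, analytic oracle, noise model."""

import numpy as np
import pytest

from bltmds import forward as fwd
from bltmds import mesh as msh
from bltmds import optics as opt


@pytest.fixture(scope="module")
def homo_small():
    """16 mm homogeneous cube at 2 mm spacing with mild optics."""
    mesh = msh.generate_box_mesh((16, 16, 16), 2.0)
    table = opt.OpticalPropertyTable()
    table.add(0, 700, 0.01, 1.0)
    return mesh, table


class TestAssembly:
    def test_symmetric_positive_definite(self, homo_small):
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        K = fem.K
        asym = abs(K - K.T).max()
        assert asym <= 1e-10 * abs(K).max()
        from scipy.sparse.linalg import eigsh

        lam_min = eigsh(K, k=1, which="SA", return_eigenvectors=False)[0]
        assert lam_min > 0

    def test_absorption_changes_only_mass(self, homo_small):
        """K(2 mu_a) - K(mu_a) must equal the mu_a mass matrix."""
        mesh, _ = homo_small
        t1, t2 = opt.OpticalPropertyTable(), opt.OpticalPropertyTable()
        mu_s = 1.0
        t1.add(0, 700, 0.01, mu_s)
        t2.add(0, 700, 0.02, mu_s)
        # keep D fixed: same mu_a + mu_s' means we must adjust mu_s
        t2.entries[(0, 700)] = opt.OpticalEntry(0.02, mu_s - 0.01)
        K1 = fwd.assemble_system(mesh, t1, 700).K
        K2 = fwd.assemble_system(mesh, t2, 700).K
        diff = (K2 - K1).toarray()
        # mass matrix of density 0.01 over the volume: row sums integrate
        # the basis, so total sum equals 0.01 * volume
        assert diff.min() >= -1e-14
        assert diff.sum() == pytest.approx(0.01 * 16.0**3, rel=1e-9)

    def test_missing_property_entry(self, homo_small):
        mesh, table = homo_small
        with pytest.raises(KeyError):
            fwd.assemble_system(mesh, table, 650)

    def test_dirichlet_flag(self, homo_small):
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700, bc="dirichlet")
        src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 1.5, 1.0))
        phi = fwd.solve_fluence(fem, src)
        # boundary fluence pinned to ~0 by the penalty
        assert np.abs(phi[mesh.boundary_nodes]).max() < 1e-9 * phi.max()


class TestSolveFluence:
    def test_zero_source(self, homo_small):
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        phi = fwd.solve_fluence(
            fem, msh.SourceDistribution(np.zeros(mesh.n_nodes), mesh)
        )
        assert np.all(phi == 0)

    def test_linearity(self, homo_small):
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 1.5, 1.0))
        phi1 = fwd.solve_fluence(fem, src)
        phi2 = fwd.solve_fluence(
            fem, msh.SourceDistribution(2.0 * src.values, mesh)
        )
        assert np.allclose(phi2, 2.0 * phi1, rtol=1e-10)

    def test_discrete_maximum_principle(self, homo_small):
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 1.5, 1.0))
        phi = fwd.solve_fluence(fem, src)
        assert phi.min() >= -1e-10 * phi.max()


class TestAnalyticOracle:
    def test_closed_form_value(self):
        phi = fwd.analytic_infinite_medium(
            np.array([[1.0, 0, 0]]), (0, 0, 0), 1.0, 0.01, 0.99
        )
        expected = np.exp(-np.sqrt(0.03)) / (4 * np.pi / 3.0)
        assert phi[0] == pytest.approx(expected, rel=1e-12)
        assert phi[0] == pytest.approx(0.2007, abs=5e-4)

    def test_monotone_decay_and_linearity(self):
        pts = np.column_stack([np.linspace(1, 10, 20), np.zeros(20), np.zeros(20)])
        phi = fwd.analytic_infinite_medium(pts, (0, 0, 0), 1.0, 0.05, 2.0)
        assert np.all(np.diff(phi) < 0)
        phi2 = fwd.analytic_infinite_medium(pts, (0, 0, 0), 2.0, 0.05, 2.0)
        assert np.allclose(phi2, 2 * phi)

    def test_source_point_rejected(self):
        with pytest.raises(ValueError):
            fwd.analytic_infinite_medium(
                np.array([[0.0, 0, 0]]), (0, 0, 0), 1.0, 0.01, 1.0
            )

    def test_fem_agreement_interior(self):
        """FEM vs infinite-medium Green's function, away from boundaries."""
        mesh = msh.generate_box_mesh((24, 24, 24), 1.0)
        table = opt.OpticalPropertyTable()
        table.add(0, 700, 0.01, 1.0)
        fem = fwd.assemble_system(mesh, table, 700)
        src = msh.embed_spherical_source(
            mesh, msh.SourceSpec((12, 12, 12), 0.4, 1.0)
        )
        phi = fwd.solve_fluence(fem, src)
        r = np.linalg.norm(mesh.nodes - [12, 12, 12], axis=1)
        mask = (r >= 3) & (r <= 6)
        ana = fwd.analytic_infinite_medium(
            mesh.nodes[mask], (12, 12, 12), 1.0, 0.01, 1.0
        )
        rel = np.abs(phi[mask] - ana) / ana
        assert rel.max() < 0.10

    def test_grid_convergence(self):
        """Halving the spacing reduces the mean error vs the oracle."""
        errors = []
        for spacing in (2.0, 1.0):
            mesh = msh.generate_box_mesh((16, 16, 16), spacing)
            table = opt.OpticalPropertyTable()
            table.add(0, 700, 0.02, 1.5)
            fem = fwd.assemble_system(mesh, table, 700)
            src = msh.embed_spherical_source(
                mesh, msh.SourceSpec((8, 8, 8), spacing / 4, 1.0)
            )
            phi = fwd.solve_fluence(fem, src)
            r = np.linalg.norm(mesh.nodes - [8, 8, 8], axis=1)
            mask = (r >= 3) & (r <= 5)
            ana = fwd.analytic_infinite_medium(
                mesh.nodes[mask], (8, 8, 8), 1.0, 0.02, 1.5
            )
            errors.append(np.mean(np.abs(phi[mask] - ana) / ana))
        assert errors[1] < errors[0]


class TestSystemMatrix:
    def test_adjoint_equals_direct(self, homo_small):
        """Adjoint construction vs brute-force per-column solves."""
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        detectors = fwd.DetectorSet(tuple(mesh.boundary_nodes[::40]))
        perm = np.setdiff1d(np.arange(mesh.n_nodes), mesh.boundary_nodes)[:50]
        A = fwd.build_system_matrix(
            mesh, table, 700, detectors, perm, fem=fem
        ).matrix
        lumped = mesh.lumped_node_volumes()
        direct = np.empty_like(A)
        for j, node in enumerate(perm):
            e = np.zeros(mesh.n_nodes)
            e[node] = lumped[node]
            direct[:, j] = fem.solve(e)[detectors.index_array()]
        assert np.abs(A - direct).max() <= 1e-9

    def test_matches_full_solve(self, homo_small):
        """A @ S equals the detector restriction of the fluence solve."""
        mesh, table = homo_small
        fem = fwd.assemble_system(mesh, table, 700)
        detectors = fwd.DetectorSet(tuple(mesh.boundary_nodes[::10]))
        sm = fwd.build_system_matrix(mesh, table, 700, detectors, fem=fem)
        src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 2.0, 1.0))
        phi = fwd.solve_fluence(fem, src)
        pred = sm.matrix @ src.values
        ref = phi[detectors.index_array()]
        assert np.allclose(pred, ref, rtol=1e-8)

    def test_shape_and_validation(self, homo_small):
        mesh, table = homo_small
        detectors = fwd.DetectorSet(tuple(mesh.boundary_nodes[:7]))
        sm = fwd.build_system_matrix(mesh, table, 700, detectors, [0, 1, 2])
        assert sm.matrix.shape == (7, 3)
        with pytest.raises(ValueError):
            fwd.build_system_matrix(mesh, table, 700, detectors, [])
        interior = np.setdiff1d(np.arange(mesh.n_nodes), mesh.boundary_nodes)
        with pytest.raises(ValueError, match="boundary"):
            fwd.build_system_matrix(
                mesh, table, 700, fwd.DetectorSet((int(interior[0]),))
            )


@pytest.fixture(scope="module")
def measured(homo_small):
    mesh, table = homo_small
    fem = fwd.assemble_system(mesh, table, 700)
    src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 1.5, 1.0))
    detectors = fwd.DetectorSet.from_boundary(mesh)
    return mesh, table, fem, src, detectors


class TestMeasurementNoise:
    def test_clean_equals_restriction(self, measured):
        mesh, table, fem, src, detectors = measured
        m = fwd.simulate_measurement(mesh, table, 700, src, detectors, fem=fem)
        phi = fwd.solve_fluence(fem, src)
        assert np.array_equal(m.values, phi[detectors.index_array()])
        assert not m.noisy

    def test_constant_offset_exact(self, measured):
        mesh, table, fem, src, detectors = measured
        noise = fwd.NoiseModel(
            seed=3, sampling_amplitude={700: 0.0}, sampling_width_mm={700: 5.0},
            offset_level=0.25, offset_sigma=0.0,
        )
        m = fwd.simulate_measurement(
            mesh, table, 700, src, detectors, noise=noise, fem=fem
        )
        assert np.array_equal(m.values, m.clean + 0.25)

    def test_seed_determinism(self, measured):
        mesh, table, fem, src, detectors = measured
        noise = fwd.NoiseModel(
            seed=11, sampling_amplitude={700: 0.01}, sampling_width_mm={700: 5.0},
            offset_level=0.001, offset_sigma=0.0005,
        )
        m1 = fwd.simulate_measurement(
            mesh, table, 700, src, detectors, noise=noise, fem=fem
        )
        m2 = fwd.simulate_measurement(
            mesh, table, 700, src, detectors, noise=noise, fem=fem
        )
        m3 = fwd.simulate_measurement(
            mesh, table, 700, src, detectors, noise=noise, seed=12, fem=fem
        )
        assert np.array_equal(m1.values, m2.values)
        assert not np.array_equal(m1.values, m3.values)

    def test_offset_shared_across_wavelengths(self, homo_small):
        """Ot realization must be bitwise identical at every wavelength."""
        mesh, _ = homo_small
        table = opt.single_region_properties("muscle", (610, 670))
        src = msh.embed_spherical_source(mesh, msh.SourceSpec((8, 8, 8), 1.5, 1.0))
        detectors = fwd.DetectorSet.from_boundary(mesh)
        clean = {
            w: fwd.simulate_measurement(mesh, table, w, src, detectors)
            for w in (610, 670)
        }
        noise = fwd.default_noise_model(
            {w: clean[w].values for w in (610, 670)}, seed=5
        )
        ot = noise.offset(len(detectors))
        assert np.array_equal(noise.offset(len(detectors)), ot)
        s610 = noise.sampling_error(610, detectors.positions(mesh),
                                    clean[610].values)
        s670 = noise.sampling_error(670, detectors.positions(mesh),
                                    clean[670].values)
        assert not np.array_equal(s610, s670)

    def test_measurement_csv_round_trip(self, measured, tmp_path):
        mesh, table, fem, src, detectors = measured
        m = fwd.simulate_measurement(mesh, table, 700, src, detectors, fem=fem)
        path = tmp_path / "meas.csv"
        fwd.write_measurement(m, mesh, path)
        back = fwd.read_measurement(path)
        assert back.wavelength == 700
        assert back.detectors.nodes == detectors.nodes
        assert np.allclose(back.values, m.values, rtol=1e-11)
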