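"""TPS boundary conditions, graded meshing and the nonlinear FEM solve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctfm.material import OgdenMaterial, SUBSTRATE_9_10, nominal_stress_uniaxial
from ctfm.spectral import layer_traction
from ctfm.traction_fem import (FEASolver, FEMError, SubstrateModel,
                               build_mesh, first_pk_stress, cauchy_stress,
                               interpolate_bc, solve)

MAT = SUBSTRATE_9_10


class TestTPS:
    @pytest.fixture()
    def scatter(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 10, (40, 2))
        u = rng.normal(0, 0.3, (40, 2))
        return xy, u

    def test_exact_at_data_points(self, scatter):
        xy, u = scatter
        got = interpolate_bc(xy, u, xy)
        assert np.abs(got - u).max() < 1e-8

    @settings(deadline=None, max_examples=20)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(-0.5, 0.5),
           c=st.floats(-0.5, 0.5), d=st.floats(-0.5, 0.5),
           tx=st.floats(-1, 1), ty=st.floats(-1, 1))
    def test_affine_fields_reproduced_everywhere(self, a, b, c, d, tx, ty):
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 8, (25, 2))
        A = np.array([[a, b], [c, d]])
        u = xy @ A.T + [tx, ty]
        query = rng.uniform(-2, 10, (30, 2))
        got = interpolate_bc(xy, u, query)
        assert np.abs(got - (query @ A.T + [tx, ty])).max() < 1e-6

    def test_zero_data_zero_everywhere(self, scatter):
        xy, _ = scatter
        got = interpolate_bc(xy, np.zeros((len(xy), 2)),
                             np.random.default_rng(1).uniform(0, 10, (20, 2)))
        assert np.abs(got).max() < 1e-12

    def test_duplicate_positions_rejected(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(FEMError, match="duplicate"):
            interpolate_bc(xy, np.zeros((4, 2)), xy)


class TestBuildMesh:
    def test_volume_conservation(self):
        model = SubstrateModel(height=30.0, L0=1.5)
        mesh = build_mesh(model, extent=(0, 20, 0, 18))
        assert mesh.volume() == pytest.approx(20 * 18 * 30, rel=1e-9)

    def test_refined_zone_element_size(self):
        """Fine elements are L0/5 ~ 0.3 um for L0 = 1.5 um."""
        model = SubstrateModel(height=10.0, L0=1.5)
        assert model.fine == pytest.approx(0.3)
        mesh = build_mesh(model, extent=(0, 10, 0, 10),
                          refined_box=(4, 6, 4, 6))
        xs = np.unique(mesh.nodes[:, 0])
        inside = xs[(xs >= 4) & (xs <= 6)]
        assert np.diff(inside).max() == pytest.approx(0.3, rel=0.1)

    def test_element_count_scales_with_fine_size(self):
        """Halving the fine size over a fixed refined region grows the
        refined-region element count by ~8x (2x per axis)."""
        counts = []
        for fine in (1.0, 0.5):
            model = SubstrateModel(height=8.0, L0=1.5, fine=fine, coarse=1.5,
                                   coarse_z=1.5, surface_band=2.0)
            mesh = build_mesh(model, extent=(0, 12, 0, 12),
                              refined_box=(3, 9, 3, 9))
            centers = mesh.nodes[mesh.tets].mean(axis=1)
            sel = ((centers[:, 0] > 3) & (centers[:, 0] < 9)
                   & (centers[:, 1] > 3) & (centers[:, 1] < 9)
                   & (centers[:, 2] > 6.0))
            counts.append(sel.sum())
        assert counts[1] / counts[0] == pytest.approx(8.0, rel=0.35)


class TestOgdenStress:
    def test_uniaxial_deviatoric_difference_matches_closed_form(self):
        """sigma_11 - sigma_22 is pressure-free: equals lambda * P_uni."""
        for lam in (1.2, 1.6, 2.2):
            F = np.diag([lam, lam ** -0.5, lam ** -0.5])
            s = cauchy_stress(F[None], MAT)[0]
            expect = lam * nominal_stress_uniaxial(MAT, lam)
            assert s[0, 0] - s[1, 1] == pytest.approx(expect, rel=1e-9)

    def test_stress_free_at_identity(self):
        P = first_pk_stress(np.eye(3)[None], MAT)[0]
        assert np.abs(P).max() < 1e-12

    def test_rotation_objectivity(self):
        rng = np.random.default_rng(2)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        P1 = first_pk_stress((R @ F)[None], MAT)[0]
        P2 = R @ first_pk_stress(F[None], MAT)[0]
        assert np.abs(P1 - P2).max() < 1e-9


@pytest.fixture(scope="module")
def shear_mesh():
    model = SubstrateModel(height=30.0, L0=1.5)
    return model, build_mesh(model, extent=(0, 15, 0, 12))


class TestSolve:
    def test_zero_bc_zero_tractions(self, shear_mesh):
        model, mesh = shear_mesh
        tf, _ = solve(model, mesh, np.zeros((len(mesh.top), 3)))
        assert np.abs(tf.traction).max() < 1e-9

    def test_simple_shear_patch(self, shear_mesh):
        """Uniform tangential top displacement with consistent lateral BC
        recovers the closed-form shear traction mu0 * u / h within 2%."""
        model, mesh = shear_mesh
        gamma = 1e-3
        bc = np.zeros((len(mesh.top), 3))
        bc[:, 0] = gamma * model.height
        tf, _ = solve(model, mesh, bc,
                      bc_lateral=lambda X: np.array([gamma * X[2], 0.0, 0.0]))
        expect = 1e3 * MAT.mu0 * gamma
        got = tf.traction[tf.central_mask(3.0), 0].mean()
        assert got == pytest.approx(expect, rel=0.02)

    def test_traction_scales_with_stiffness(self, shear_mesh):
        """In the linear limit, doubling both mu_i doubles the tractions."""
        model, mesh = shear_mesh
        stiff = OgdenMaterial(mu1=2 * MAT.mu1, alpha1=MAT.alpha1,
                              mu2=2 * MAT.mu2, alpha2=MAT.alpha2, nu=MAT.nu)
        model2 = SubstrateModel(height=30.0, L0=1.5, material=stiff)
        xy = mesh.nodes[mesh.top][:, :2]
        bc = np.zeros((len(mesh.top), 3))
        bc[:, 0] = 0.02 * np.exp(-((xy[:, 0] - 7.5) ** 2
                                   + (xy[:, 1] - 6) ** 2) / (2 * 2.0 ** 2))
        t1, _ = solve(model, mesh, bc)
        t2, _ = solve(model2, mesh, bc)
        m = t1.central_mask(3.0)
        ratio = t2.traction[m, 0][np.abs(t1.traction[m, 0]) > 1] \
            / t1.traction[m, 0][np.abs(t1.traction[m, 0]) > 1]
        assert np.median(ratio) == pytest.approx(2.0, rel=0.01)


@pytest.fixture(scope="module")
def bump_case():
    """Localized tangential Gaussian bump on a 24 um patch."""
    # the fine vertical band matches the bump width (the depth over which
    # the elastic fields of a sigma = 2.5 um feature decay)
    model = SubstrateModel(height=30.0, L0=1.5, fine=0.75, coarse=1.5,
                           surface_band=4.0)
    mesh = build_mesh(model, extent=(0, 24, 0, 24),
                      refined_box=(5, 19, 5, 19))
    solver = FEASolver(model, mesh)
    xy = mesh.nodes[mesh.top][:, :2]

    def bump(p, comp):
        bc = np.zeros((len(p), 3))
        bc[:, comp] = 0.05 * np.exp(-((p[:, 0] - 12) ** 2
                                      + (p[:, 1] - 12) ** 2) / (2 * 2.5 ** 2))
        return bc

    return model, mesh, solver, xy, bump


class TestAgainstLinearLayerReference:
    def test_small_strain_tractions_match_spectral_solver(self, bump_case):
        """Independent Fourier-space linear layer solution within 10%."""
        model, mesh, solver, xy, bump = bump_case
        tf, _ = solver.solve(bump(xy, 0))
        i = np.argmin(np.sum((tf.points[:, :2] - 12) ** 2, axis=1))
        n, dx = 128, 0.75
        g = (np.arange(n) + 0.5) * dx
        X, Y = np.meshgrid(g, g)
        d = np.zeros((n, n, 3))
        d[..., 0] = 0.05 * np.exp(-((X - 48) ** 2 + (Y - 48) ** 2)
                                  / (2 * 2.5 ** 2))
        ref = layer_traction(d, dx=dx, h=30.0, shear_modulus=MAT.mu0,
                             nu=MAT.nu)
        expect = 1e3 * ref[..., 0].max()
        assert tf.traction[i, 0] == pytest.approx(expect, rel=0.10)

    def test_in_plane_force_balance(self, bump_case):
        """Self-equilibrated tangential dipole: net in-plane force < 1% of
        the L1 force norm (the net normal force is the reaction to the
        imposed flat-surface constraint and is excluded)."""
        model, mesh, solver, xy, _ = bump_case
        u1 = np.exp(-((xy[:, 0] - 9) ** 2 + (xy[:, 1] - 12) ** 2) / 8.0)
        u2 = np.exp(-((xy[:, 0] - 15) ** 2 + (xy[:, 1] - 12) ** 2) / 8.0)
        bc = np.zeros((len(xy), 3))
        bc[:, 0] = 0.1 * (u2 - u1)
        tf, _ = solver.solve(bc)
        F = tf.traction * tf.area[:, None]
        net = np.abs(F[:, :2].sum(axis=0)).max()
        assert net < 0.01 * np.abs(F[:, :2]).sum()

    def test_vertical_bump_gives_dominantly_vertical_tractions(self,
                                                               bump_case):
        model, mesh, solver, xy, bump = bump_case
        tf, _ = solver.solve(bump(xy, 2))
        m = tf.central_mask(3.0)
        assert (np.abs(tf.traction[m, 2]).sum()
                > 5 * np.abs(tf.traction[m, :2]).sum())

    def test_mesh_convergence_of_bump_traction(self):
        """Halving the fine element size changes the recovered traction
        force over the bump region by < 5%.

        Nested grids (fixed fine-band depth) on a compact shallow-layer
        configuration; each mesh is solved and released before the next
        to keep peak memory modest.  The integral functional is the
        mesh-convergent statement this element affords at desk scale:
        the raw single-node peak converges only at first order in the
        element size and still moves by ~8% per halving at the largest
        affordable meshes (see the methods note).
        """
        forces = []
        for fine in (0.9, 0.45):
            model = SubstrateModel(height=12.0, L0=1.5, fine=fine,
                                   coarse=1.5, surface_band=3.0)
            mesh = build_mesh(model, extent=(0, 20, 0, 20),
                              refined_box=(5.5, 14.5, 5.5, 14.5))
            xy = mesh.nodes[mesh.top][:, :2]
            bc = np.zeros((len(xy), 3))
            bc[:, 0] = 0.05 * np.exp(-((xy[:, 0] - 10) ** 2
                                       + (xy[:, 1] - 10) ** 2)
                                     / (2 * 2.5 ** 2))
            tf, _ = solve(model, mesh, bc)
            r = np.linalg.norm(tf.points[:, :2] - 10, axis=1)
            forces.append(float((tf.traction[r < 4.0, 0]
                                 * tf.area[r < 4.0]).sum()))
            del mesh, tf
        assert forces[1] == pytest.approx(forces[0], rel=0.05)


class TestSpectralReferenceSelfChecks:
    def test_uniform_shear_limit(self):
        d = np.zeros((8, 8, 3))
        d[..., 0] = 0.01
        t = layer_traction(d, dx=1.0, h=30.0, shear_modulus=4.24, nu=0.49)
        assert t[0, 0, 0] == pytest.approx(4.24 * 0.01 / 30.0, rel=1e-9)

    def test_uniform_compression_limit(self):
        mu, nu = 4.24, 0.49
        lam = 2 * mu * nu / (1 - 2 * nu)
        d = np.zeros((8, 8, 3))
        d[..., 2] = 0.01
        t = layer_traction(d, dx=1.0, h=30.0, shear_modulus=mu, nu=nu)
        assert t[0, 0, 2] == pytest.approx((lam + 2 * mu) * 0.01 / 30.0,
                                           rel=1e-9)
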