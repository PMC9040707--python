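"""Saint Venant-Kirchhoff FEM: constitutive law, assembly, time integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import vfsim as vf
from vfsim.solid import FoldDynamics, MaterialParams, SolidState, _det3

from conftest import make_block_geometry


class TestLame:
    def test_zero_poisson_decouples(self):
        lam, mu = vf.lame_from_young(1.0, 0.0)
        assert lam == 0.0 and mu == 0.5

    @pytest.mark.parametrize("E, expected", [
        (80e3, (46153.846, 30769.231)),   # body modulus, nu = 0.3
        (8e3, (4615.385, 3076.923)),      # cover modulus, nu = 0.3
    ])
    def test_tissue_moduli_conversion(self, E, expected):
        lam, mu = vf.lame_from_young(E, 0.3)
        assert lam == pytest.approx(expected[0], rel=1e-6)
        assert mu == pytest.approx(expected[1], rel=1e-6)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(vf.VfsimError):
            vf.lame_from_young(1e3, 0.5)
        with pytest.raises(vf.VfsimError):
            vf.lame_from_young(-1.0, 0.3)


class TestKinematicsAndStress:
    def test_identity_and_stretch(self):
        assert np.allclose(vf.green_strain(np.eye(3)), 0.0)
        E = vf.green_strain(np.diag([1.1, 1.0, 1.0]))
        assert E[0, 0] == pytest.approx(0.105)
        assert np.allclose(E - np.diag([0.105, 0, 0]), 0.0, atol=1e-15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_rotation_is_strain_free(self, seed):
        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        assert np.allclose(vf.green_strain(R), 0.0, atol=1e-14)

    def test_inverted_gradient_rejected(self):
        with pytest.raises(vf.InvertedElementError):
            vf.green_strain(np.diag([-1.0, 1.0, 1.0]))

    def test_svk_stress_oracle(self):
        lam, mu = 2.0, 3.0
        assert np.allclose(vf.svk_pk2(np.zeros((3, 3)), lam, mu), 0.0)
        e = 0.01
        S = vf.svk_pk2(np.diag([e, 0, 0]), lam, mu)
        assert np.allclose(S, np.diag([(lam + 2 * mu) * e, lam * e, lam * e]))
        gamma = 0.02
        Es = np.zeros((3, 3))
        Es[0, 1] = Es[1, 0] = gamma / 2
        S = vf.svk_pk2(Es, lam, mu)
        assert S[0, 1] == pytest.approx(mu * gamma)
        assert np.allclose(np.diag(S), 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_svk_is_linear_in_strain(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        A = 0.5 * (A + A.T)
        B = rng.standard_normal((3, 3))
        B = 0.5 * (B + B.T)
        lam, mu = 1.7, 0.9
        assert np.allclose(vf.svk_pk2(2 * A + B, lam, mu),
                           2 * vf.svk_pk2(A, lam, mu)
                           + vf.svk_pk2(B, lam, mu))

    def test_det3_matches_lapack(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal((17, 3, 3))
        assert np.allclose(_det3(F), np.linalg.det(F))


@pytest.fixture(scope="module")
def single_tet_fem():
    import vfsim.mesh as vm
    nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    elems = np.array([[0, 1, 2, 3]])
    facets, _ = vm.extract_boundary(elems)
    geom = vm.LarynxGeometry(
        nodes=nodes, elements=elems,
        layer_labels=np.zeros(1, dtype=np.int32),
        boundary_facets=facets,
        boundary_tags=np.full(len(facets), vm.TAG_LUMEN, dtype=np.int32),
        lumen_axis=np.array([0.0, 1.0]),
        medial_grids=(np.zeros((1, 1), int), np.zeros((1, 1), int)),
        rigid_half_gap=np.array([1.0, 1.0]), span=1.0, fold_x_range=(0, 1),
        rest_min_area=1.0, marker_node=0)
    return FoldDynamics(geom, MaterialParams(E_body=1e3, E_cover=1e3, nu=0.3))


class TestAssembly:
    def test_zero_displacement_zero_force(self, block_fem):
        f = block_fem.internal_forces(
            np.zeros((block_fem.n_nodes, 3)))
        assert np.allclose(f, 0.0)

    def test_rigid_rotation_objectivity(self, block_fem):
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        X = block_fem.geometry.nodes
        u = X @ R.T - X
        f = block_fem.internal_forces(u)
        from vfsim.mesh import facet_areas_normals
        areas, _ = facet_areas_normals(X, block_fem.geometry.boundary_facets)
        bound = 1e-10 * block_fem.mu.max() * areas.sum()
        assert np.linalg.norm(f) < bound

    def test_uniaxial_patch_stress(self, block_fem):
        """Uniform stretch reproduces the closed-form SVK stress exactly."""
        s = 0.05
        X = block_fem.geometry.nodes
        u = np.zeros_like(X)
        u[:, 0] = s * X[:, 0]
        _, S = block_fem.element_stresses(u)
        lam, mu = block_fem.lam[0], block_fem.mu[0]
        e = 0.5 * ((1 + s) ** 2 - 1)
        S_exact = np.diag([(lam + 2 * mu) * e, lam * e, lam * e])
        assert np.max(np.abs(S - S_exact)) / np.abs(S_exact).max() < 1e-12

    def test_single_element_force_matches_energy_gradient(
            self, single_tet_fem):
        """Independent oracle: f_int must be the gradient of the stored
        strain energy (central differences per dof)."""
        fem = single_tet_fem
        rng = np.random.default_rng(7)
        u = 0.05 * rng.standard_normal((4, 3))
        f = fem.internal_forces(u)
        eps = 1e-7
        f_num = np.zeros_like(f)
        for a in range(4):
            for i in range(3):
                up, um = u.copy(), u.copy()
                up[a, i] += eps
                um[a, i] -= eps
                f_num[a, i] = (fem.strain_energy(up)
                               - fem.strain_energy(um)) / (2 * eps)
        assert np.allclose(f, f_num, rtol=1e-6, atol=1e-9)

    def test_lumped_mass_conservation(self, block_fem):
        v_total = block_fem.volumes.sum()
        assert block_fem.mass.sum() == pytest.approx(
            block_fem.material.rho_s * v_total, rel=1e-14)

    def test_tangent_consistent_with_forces(self, block_fem):
        rng = np.random.default_rng(1)
        u = 1e-4 * rng.standard_normal((block_fem.n_nodes, 3))
        w = rng.standard_normal((block_fem.n_nodes, 3))
        K = block_fem.tangent_stiffness(u)
        kw = (K @ w.reshape(-1)).reshape(-1, 3)
        assert np.allclose(kw, block_fem.tangent_apply(u, w), rtol=1e-12)
        eps = 1e-6
        fd = (block_fem.internal_forces(u + eps * w)
              - block_fem.internal_forces(u - eps * w)) / (2 * eps)
        assert np.allclose(kw, fd, rtol=1e-4, atol=1e-8 * np.abs(fd).max())


class TestTraction:
    def test_zero_pressure_zero_force(self, block_fem):
        nf = len(block_fem.geometry.lumen_facets)
        f = block_fem.apply_traction(np.zeros(nf))
        assert np.allclose(f, 0.0)

    def test_uniform_pressure_on_closed_surface(self):
        geom = make_block_geometry(clamp="none")
        fem = FoldDynamics(geom, MaterialParams(E_body=1e3, E_cover=1e3))
        nf = len(geom.lumen_facets)
        p0 = 100.0
        f = fem.apply_traction(np.full(nf, p0))
        from vfsim.mesh import facet_areas_normals
        areas, _ = facet_areas_normals(geom.nodes, geom.boundary_facets)
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * p0 * areas.sum()

    def test_flat_patch_resultant(self, block_fem):
        """Uniform p on the clamped-block lumen faces: the x = L face alone
        contributes -p * area * x-hat."""
        geom = block_fem.geometry
        facets = geom.lumen_facets
        cx = geom.nodes[facets].mean(axis=1)[:, 0]
        L = geom.nodes[:, 0].max()
        p = np.where(np.isclose(cx, L), 50.0, 0.0)
        f = block_fem.apply_traction(p)
        area = geom.span * geom.nodes[:, 2].max()
        assert f.sum(axis=0)[0] == pytest.approx(-50.0 * area, rel=1e-12)
        assert abs(f.sum(axis=0)[1]) < 1e-12
        assert abs(f.sum(axis=0)[2]) < 1e-12

    def test_wrong_facet_count_rejected(self, block_fem):
        with pytest.raises(vf.VfsimError, match="lumen"):
            block_fem.apply_traction(np.zeros(3))


class TestNewmark:
    def test_equilibrium_is_preserved(self, block_fem):
        state = SolidState.rest(block_fem.n_nodes)
        out = block_fem.newmark_step(
            state, np.zeros((block_fem.n_nodes, 3)), dt=1e-4)
        assert np.allclose(out.displacement, 0.0)
        assert np.allclose(out.velocity, 0.0)

    def test_small_amplitude_matches_harmonic_oracle(self):
        """Linearized free vibration in the first mode follows cos(w t)
        within 1% after one period at 200 steps/period."""
        geom = make_block_geometry(2, 2, 2)
        fem = FoldDynamics(geom, MaterialParams(E_body=5e3, E_cover=5e3,
                                                nu=0.0, rayleigh_beta=0.0))
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        K = fem.tangent_stiffness(np.zeros((fem.n_nodes, 3)))
        fd = fem.free_dofs
        M = sp.diags(np.repeat(fem.mass, 3)[fd])
        vals, vecs = spla.eigsh(K[fd][:, fd], k=1, M=M, sigma=0, which="LM")
        omega = np.sqrt(vals[0])
        amp = 1e-7
        phi = np.zeros(fem.n_dof)
        phi[fd] = vecs[:, 0]
        u0 = amp * phi.reshape(-1, 3) / np.abs(phi).max()
        state = SolidState(u0, np.zeros_like(u0), np.zeros_like(u0))
        state.acceleration = fem.initial_acceleration(
            state, np.zeros_like(u0))
        T = 2 * np.pi / omega
        dt = T / 200
        zeros = np.zeros_like(u0)
        for _ in range(200):
            state = fem.newmark_step(state, zeros, dt, tol=1e-11)
        err = np.linalg.norm(state.displacement - u0) / np.linalg.norm(u0)
        assert err < 0.01

    def test_free_vibration_energy_drift_short(self, block_fem):
        fem = block_fem
        state = SolidState.rest(fem.n_nodes)
        state.velocity[:, 2] = 1e-3 * fem.geometry.nodes[:, 0] / 1e-2
        state.velocity[~fem.free_nodes] = 0.0
        zeros = np.zeros((fem.n_nodes, 3))
        state.acceleration = fem.initial_acceleration(state, zeros)
        E0 = fem.kinetic_energy(state.velocity)
        f1 = fem.modal_frequencies(1)[0]
        dt = 1.0 / (40 * f1)
        for _ in range(10 * 40):          # ten periods
            state = fem.newmark_step(state, zeros, dt, tol=1e-10)
        E = fem.kinetic_energy(state.velocity) \
            + fem.strain_energy(state.displacement)
        assert abs(E - E0) / E0 < 1e-3

    def test_nonconvergence_reports_residual_history(self, block_fem):
        state = SolidState.rest(block_fem.n_nodes)
        f = np.zeros((block_fem.n_nodes, 3))
        f[block_fem.free_nodes, 2] = 1e3   # brutal load, 1 iteration allowed
        with pytest.raises(vf.ConvergenceError) as exc:
            block_fem.newmark_step(state, f, dt=1e-3, max_iter=1)
        assert len(exc.value.residual_history) >= 1


def test_hyperelastic_conservativity_closed_cycle(block_fem):
    """The internal force is a potential gradient: net work around a closed
    deformation cycle vanishes relative to the peak strain energy."""
    fem = block_fem
    rng = np.random.default_rng(11)
    mode_a = 1e-4 * rng.standard_normal((fem.n_nodes, 3))
    mode_b = 1e-4 * rng.standard_normal((fem.n_nodes, 3))
    thetas = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    dth = thetas[1] - thetas[0]
    work = 0.0
    peak = 0.0
    for th in thetas:
        u = np.sin(th) * mode_a + np.sin(2 * th) * mode_b
        du = np.cos(th) * mode_a + 2 * np.cos(2 * th) * mode_b
        work += np.sum(fem.internal_forces(u) * du) * dth
        peak = max(peak, fem.strain_energy(u))
    assert abs(work) < 0.005 * peak


def test_modal_frequency_scales_with_sqrt_modulus(coarse_geometry):
    f_base = vf.FoldDynamics(
        coarse_geometry, MaterialParams(E_body=80e3, E_cover=8e3)
    ).modal_frequencies(1)[0]
    f_stiff = vf.FoldDynamics(
        coarse_geometry, MaterialParams(E_body=4 * 80e3, E_cover=4 * 8e3)
    ).modal_frequencies(1)[0]
    assert f_stiff / f_base == pytest.approx(2.0, rel=0.01)
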