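"""Finite-strain Saint Venant-Kirchhoff finite-element dynamics.

Two-layer (body/cover) vocal-fold tissue on 4-node linear tetrahedra with
single-point quadrature, fixed exterior boundary, follower pressure loads on
the lumen surface, light Rayleigh damping, and implicit Newmark-beta time
integration with Newton sub-iterations.

The constitutive model is hyperelastic with second Piola-Kirchhoff stress

    S = lambda tr(E) I + 2 mu E,      E = (F^T F - I) / 2,

which is objective under finite rotations.  The internal nodal force of an
element is the single-point quadrature of P : grad(N) with P = F S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, InvertedElementError, VfsimError
from .mesh import LarynxGeometry, LAYER_COVER, TAG_LUMEN

_I3 = np.eye(3)


@dataclass
class MaterialParams:
    """Isotropic two-layer tissue parameters.

    Density and Poisson ratio default to soft-tissue values (1000 kg/m^3,
    0.3); Rayleigh damping defaults to a stiffness-proportional amount of
    a few percent of critical at phonation frequencies, which also bounds
    the collision-limited vibration cycle (fold contact is not modeled).
    """

    E_body: float = 80e3       # Pa
    E_cover: float = 8e3       # Pa
    nu: float = 0.3
    rho_s: float = 1000.0      # kg/m^3
    rayleigh_alpha: float = 0.0    # 1/s, mass proportional
    rayleigh_beta: float = 3e-5    # s, tangent-stiffness proportional

    def validate(self) -> None:
        if self.E_body <= 0 or self.E_cover <= 0:
            raise VfsimError("Young's moduli must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise VfsimError(
                f"Poisson ratio must be in [0, 0.5), got {self.nu} "
                "(incompressible limit unsupported)")
        if self.rho_s <= 0:
            raise VfsimError("tissue density must be positive")
        if self.rayleigh_alpha < 0 or self.rayleigh_beta < 0:
            raise VfsimError("Rayleigh coefficients must be non-negative")


def lame_from_young(E: float, nu: float):
    """First and second Lame parameters from Young's modulus and Poisson ratio."""
    if E <= 0:
        raise VfsimError(f"Young's modulus must be positive, got {E}")
    if not 0.0 <= nu < 0.5:
        raise VfsimError(
            f"Poisson ratio must be in [0, 0.5), got {nu} "
            "(incompressible limit unsupported)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def _det3(F: np.ndarray) -> np.ndarray:
    """Determinants of batched 3x3 matrices (faster than np.linalg.det)."""
    return (F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2]
                            - F[..., 1, 2] * F[..., 2, 1])
            - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2]
                              - F[..., 1, 2] * F[..., 2, 0])
            + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1]
                              - F[..., 1, 1] * F[..., 2, 0]))


def green_strain(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2; batched over leading axes."""
    F = np.asarray(F, dtype=float)
    detF = _det3(F)
    if np.any(detF <= 0):
        bad = int(np.argmin(detF.reshape(-1)))
        raise InvertedElementError(bad, float(detF.reshape(-1)[bad]))
    return 0.5 * (np.swapaxes(F, -1, -2) @ F - _I3)


def svk_pk2(E_green: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress of the Saint Venant-Kirchhoff law."""
    E_green = np.asarray(E_green, dtype=float)
    tr = np.trace(E_green, axis1=-2, axis2=-1)
    return lam * tr[..., None, None] * _I3 + 2.0 * mu * E_green


@dataclass
class SolidState:
    """Nodal kinematics of the tissue at one instant."""

    displacement: np.ndarray   # (n, 3) m
    velocity: np.ndarray       # (n, 3) m/s
    acceleration: np.ndarray   # (n, 3) m/s^2
    time: float = 0.0

    @classmethod
    def rest(cls, n_nodes: int, time: float = 0.0) -> "SolidState":
        z = np.zeros((n_nodes, 3))
        return cls(z, z.copy(), z.copy(), time)

    def copy(self) -> "SolidState":
        return SolidState(self.displacement.copy(), self.velocity.copy(),
                          self.acceleration.copy(), self.time)


class FoldDynamics:
    """Assembled FEM operators and time stepping for one geometry/material."""

    def __init__(self, geometry: LarynxGeometry, material: MaterialParams):
        material.validate()
        self.geometry = geometry
        self.material = material
        nodes, elems = geometry.nodes, geometry.elements
        self.n_nodes = nodes.shape[0]
        self.n_dof = 3 * self.n_nodes

        x = nodes[elems]                       # (ne, 4, 3)
        d = x[:, 1:] - x[:, :1]                # (ne, 3, 3) rows = edges
        # natural-coordinate rows: x = X0 + D^T xi  with D rows as edges
        dmat = np.swapaxes(d, -1, -2)          # columns = edges
        self.volumes = np.linalg.det(dmat) / 6.0
        if np.any(self.volumes <= 0):
            bad = int(np.argmin(self.volumes))
            raise InvertedElementError(bad, float(self.volumes[bad]))
        dinv = np.linalg.inv(dmat)             # (ne, 3, 3); row a = grad xi_a
        grads = np.empty((len(elems), 4, 3))
        grads[:, 1:, :] = dinv
        grads[:, 0, :] = -dinv.sum(axis=1)
        self.grads = grads                     # grad N_a, (ne, 4, 3)

        lam_b, mu_b = lame_from_young(material.E_body, material.nu)
        lam_c, mu_c = lame_from_young(material.E_cover, material.nu)
        cover = geometry.layer_labels == LAYER_COVER
        self.lam = np.where(cover, lam_c, lam_b)
        self.mu = np.where(cover, mu_c, mu_b)

        # lumped mass
        m = np.zeros(self.n_nodes)
        np.add.at(m, elems.ravel(),
                  np.repeat(material.rho_s * self.volumes / 4.0, 4))
        self.mass = m                                   # (n,) per node

        free = np.ones(self.n_nodes, dtype=bool)
        free[geometry.fixed_nodes] = False
        self.free_nodes = free
        self.free_dofs = np.repeat(free, 3)

        # precomputed sparse assembly: CSR pattern once, then bincount fills
        edof = (3 * elems[:, :, None] + np.arange(3)).reshape(-1, 12)
        rows = np.repeat(edof, 12, axis=1).ravel()
        cols = np.tile(edof, (1, 12)).ravel()
        pattern = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.n_dof, self.n_dof)).tocsr()
        pattern.sort_indices()
        self._csr_indptr = pattern.indptr
        self._csr_indices = pattern.indices
        keys_csr = (np.repeat(np.arange(self.n_dof),
                              np.diff(pattern.indptr)).astype(np.int64)
                    * self.n_dof + pattern.indices)
        self._data_idx = np.searchsorted(keys_csr,
                                         rows.astype(np.int64) * self.n_dof
                                         + cols)
        self._nnz = pattern.nnz
        self._newmark_cache = None

        self._elem_flat = elems.ravel()

        # lumen facet bookkeeping for traction application
        self._lumen_facets = geometry.boundary_facets[
            geometry.boundary_tags == TAG_LUMEN]

    # -- kinematics and forces ---------------------------------------------

    def _scatter(self, fe: np.ndarray) -> np.ndarray:
        """Sum per-element nodal vectors (ne, 4, 3) into global (n, 3)."""
        flat = fe.reshape(-1, 3)
        out = np.empty((self.n_nodes, 3))
        for i in range(3):
            out[:, i] = np.bincount(self._elem_flat, weights=flat[:, i],
                                    minlength=self.n_nodes)
        return out

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.geometry.elements]                  # (ne, 4, 3)
        # F_iJ = I + sum_a u_a,i gradN_a,J  as a batched matmul
        return _I3 + np.swapaxes(ue, 1, 2) @ self.grads

    def element_stresses(self, u: np.ndarray):
        """(F, S) per element; raises on inverted elements."""
        F = self.deformation_gradients(u)
        E = green_strain(F)
        tr = np.trace(E, axis1=-2, axis2=-1)
        S = (self.lam * tr)[:, None, None] * _I3 + 2.0 * self.mu[:, None, None] * E
        return F, S

    def internal_forces(self, u: np.ndarray) -> np.ndarray:
        """Assembled internal nodal forces (n, 3); zero at rest."""
        F, S = self.element_stresses(u)
        P = F @ S
        fe = self.volumes[:, None, None] * (
            self.grads @ np.swapaxes(P, 1, 2))
        return self._scatter(fe)

    def strain_energy(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        E = green_strain(F)
        tr = np.trace(E, axis1=-2, axis2=-1)
        psi = 0.5 * self.lam * tr ** 2 + self.mu * np.einsum("eij,eij->e", E, E)
        return float(np.sum(self.volumes * psi))

    def kinetic_energy(self, v: np.ndarray) -> float:
        return 0.5 * float(np.sum(self.mass * np.sum(v * v, axis=1)))

    def tangent_stiffness(self, u: np.ndarray) -> sp.csr_matrix:
        """Consistent tangent d f_int / d u as a sparse (3n, 3n) matrix."""
        F, S = self.element_stresses(u)
        G = self.grads
        H = np.einsum("eiJ,eaJ->eai", F, G)             # F grad(N_a)
        GSG = np.einsum("eaJ,eJK,ebK->eab", G, S, G)
        GG = np.einsum("eaJ,ebJ->eab", G, G)
        B = F @ np.swapaxes(F, -1, -2)
        V, lam, mu = self.volumes, self.lam, self.mu
        K = (np.einsum("e,eab,ij->eaibj", V, GSG, _I3)
             + np.einsum("e,eai,ebj->eaibj", V * lam, H, H)
             + np.einsum("e,ebi,eaj->eaibj", V * mu, H, H)
             + np.einsum("e,eij,eab->eaibj", V * mu, B, GG))
        data = np.bincount(self._data_idx, weights=K.reshape(-1),
                           minlength=self._nnz)
        return sp.csr_matrix((data, self._csr_indices, self._csr_indptr),
                             shape=(self.n_dof, self.n_dof))

    def tangent_apply(self, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Directional derivative of f_int at u along w (matrix-free K_t w)."""
        F, S = self.element_stresses(u)
        we = w[self.geometry.elements]
        dF = np.swapaxes(we, 1, 2) @ self.grads
        dE = 0.5 * (np.swapaxes(F, -1, -2) @ dF + np.swapaxes(dF, -1, -2) @ F)
        tr = np.trace(dE, axis1=-2, axis2=-1)
        dS = (self.lam * tr)[:, None, None] * _I3 \
            + 2.0 * self.mu[:, None, None] * dE
        dP = dF @ S + F @ dS
        fe = self.volumes[:, None, None] * (
            self.grads @ np.swapaxes(dP, 1, 2))
        return self._scatter(fe)

    def damping_force(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Rayleigh damping force (alpha M + beta K_t(u)) v."""
        a, b = self.material.rayleigh_alpha, self.material.rayleigh_beta
        f = np.zeros((self.n_nodes, 3))
        if a:
            f += a * self.mass[:, None] * v
        if b:
            f += b * self.tangent_apply(u, v)
        return f

    # -- surface loads -------------------------------------------------------

    def apply_traction(self, facet_pressures: np.ndarray,
                       displacements: np.ndarray | None = None) -> np.ndarray:
        """Consistent nodal forces from lumen-facet pressures (follower load).

        ``facet_pressures`` is ordered like ``geometry.lumen_facets``.  The
        traction on the solid is -p n dS with n the outward (into-lumen)
        normal of the *deformed* surface; fixed-node entries remain in the
        returned array and are eliminated by the constraint handling of the
        solver.
        """
        facets = self._lumen_facets
        p = np.asarray(facet_pressures, dtype=float)
        if p.shape != (len(facets),):
            raise VfsimError(
                f"pressure field shape {p.shape} does not match the "
                f"{len(facets)} lumen facets (pressure on non-lumen facets?)")
        x = self.geometry.nodes
        if displacements is not None:
            x = x + displacements
        tri = x[facets]
        # outward area vector (2 * area * n) / 2
        an = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        contrib = (-p[:, None] * an) / 3.0
        f = np.zeros((self.n_nodes, 3))
        for a in range(3):
            np.add.at(f, facets[:, a], contrib)
        return f

    def lumen_facet_geometry(self, displacements: np.ndarray | None = None):
        """(centroids, area-weighted outward normals) of deformed lumen facets."""
        x = self.geometry.nodes
        if displacements is not None:
            x = x + displacements
        tri = x[self._lumen_facets]
        an = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return tri.mean(axis=1), an

    # -- modal analysis ------------------------------------------------------

    def modal_frequencies(self, k: int = 4) -> np.ndarray:
        """First k natural frequencies (Hz) of the linearized, undamped fold."""
        K = self.tangent_stiffness(np.zeros((self.n_nodes, 3)))
        fd = self.free_dofs
        Kff = K[fd][:, fd]
        M = sp.diags(np.repeat(self.mass, 3)[fd])
        vals = spla.eigsh(Kff, k=k, M=M, sigma=0, which="LM",
                          return_eigenvectors=False)
        vals = np.sort(np.abs(vals))
        return np.sqrt(vals) / (2.0 * np.pi)

    # -- time integration ----------------------------------------------------

    def initial_acceleration(self, state: SolidState,
                             f_ext: np.ndarray) -> np.ndarray:
        """Consistent a0 = M^-1 (f_ext - f_int - f_damp) on free dofs."""
        r = f_ext - self.internal_forces(state.displacement) \
            - self.damping_force(state.displacement, state.velocity)
        a = np.zeros_like(r)
        fn = self.free_nodes
        a[fn] = r[fn] / self.mass[fn, None]
        return a

    def newmark_step(self, state: SolidState, f_ext, dt: float,
                     beta: float = 0.25, gamma: float = 0.5,
                     tol: float = 1e-9, max_iter: int = 30) -> SolidState:
        """Advance M a + C v + f_int(u) = f_ext by one implicit Newmark step.

        ``f_ext`` may be a (n, 3) array or a callable ``f_ext(u)`` for
        follower loads (its load stiffness is neglected in the Jacobian).
        Newton iterates until the residual drops below ``tol`` relative to a
        force scale; non-convergence raises :class:`ConvergenceError` with
        the residual history.
        """
        if dt <= 0:
            raise VfsimError("dt must be positive")
        fext_fun = f_ext if callable(f_ext) else (lambda u: f_ext)
        u_n, v_n, a_n = state.displacement, state.velocity, state.acceleration
        u_tilde = u_n + dt * v_n + dt * dt * (0.5 - beta) * a_n
        v_tilde = v_n + dt * (1.0 - gamma) * a_n
        c_a = 1.0 / (beta * dt * dt)
        c_v = gamma / (beta * dt)

        alpha, rbeta = self.material.rayleigh_alpha, self.material.rayleigh_beta
        fd = self.free_dofs
        m3 = np.repeat(self.mass, 3)[fd]

        # the Jacobian is dominated by the near-constant mass term, so a
        # cached factorization is reused (modified Newton) and refreshed
        # only when the iteration contracts poorly; the residual itself is
        # always exact, so the converged state is unaffected.
        cache_key = (dt, beta, gamma)
        lu = None
        if self._newmark_cache and self._newmark_cache[0] == cache_key:
            lu = self._newmark_cache[1]

        def refactor(u_lin):
            Kt = self.tangent_stiffness(u_lin)
            J = Kt[fd][:, fd] * (1.0 + c_v * rbeta) \
                + sp.diags(m3 * (c_a + c_v * alpha))
            fresh = spla.splu(J.tocsc())
            self._newmark_cache = (cache_key, fresh)
            return fresh

        u = u_n.copy()
        history = []
        scale = None
        fresh_jacobian = lu is None
        for it in range(max_iter):
            a = c_a * (u - u_tilde)
            v = v_tilde + gamma * dt * a
            f_int = self.internal_forces(u)
            f_e = fext_fun(u)
            res = (self.mass[:, None] * a + f_int
                   + self.damping_force(u, v) - f_e)
            r = res.reshape(-1)[fd]
            rn = np.linalg.norm(r)
            if scale is None:
                scale = max(np.linalg.norm(f_e.reshape(-1)[fd]),
                            np.linalg.norm(f_int.reshape(-1)[fd]),
                            np.linalg.norm(m3 * a.reshape(-1)[fd]), 1e-12)
            history.append(rn / scale)
            if rn <= tol * scale:
                break
            # stagnation at the round-off floor counts as converged
            if (len(history) >= 3 and rn <= 1e-6 * scale
                    and history[-1] > 0.5 * history[-3]):
                break
            slow = len(history) > 1 and history[-1] > 0.2 * history[-2]
            if lu is None or (slow and not fresh_jacobian):
                lu = refactor(u)
                fresh_jacobian = True
            elif slow and fresh_jacobian and it > 2:
                fresh_jacobian = False   # allow one more refactor later
            du = lu.solve(-r)
            u = u.copy()
            u.reshape(-1)[fd] += du
        else:
            raise ConvergenceError(
                f"Newmark-Newton failed to converge in {max_iter} iterations",
                residual_history=history)
        a = c_a * (u - u_tilde)
        v = v_tilde + gamma * dt * a
        # enforce exact zeros on constrained dofs
        fixed = ~self.free_nodes
        for arr in (u, v, a):
            arr[fixed] = 0.0
        return SolidState(u, v, a, state.time + dt)
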