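"""Staggered finite-element solver for the coupled rupture problem.

Spatial discretization uses standard displacement-based elements (4-node
quadrilaterals in plane strain, 4-node tetrahedra in 3-D) for both the
deformation map and the crack phase field.  Each pseudo-time increment is
solved with the one-pass operator split:

1. mechanics: Newton iteration on the balance of linear momentum at the
   phase field frozen from the previous step (total-Lagrangian assembly of
   the first Piola-Kirchhoff stress and its consistent tangent, follower
   pressure on tagged surfaces with load-stiffness contribution);
2. history: the crack driving source Hbar is evaluated from the effective
   energies at each quadrature point and the irreversible history field
   H <- max(H, <Hbar - 1>) is updated;
3. phase field: one sparse symmetric positive-definite linear solve for the
   nodal d, followed by a projection onto [d_n, 1] which enforces bounds and
   nodal irreversibility on coarse meshes.

Exactly one pass, no sub-iteration; the scheme is deterministic.  Newton
failure triggers pseudo-time step halving down to ``dt_min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as co
from . import phasefield as pfm
from .constitutive import FiberFrame, MaterialParams
from .mesh import Mesh
from .phasefield import PhaseFieldParams

__all__ = [
    "SolverSettings",
    "DirichletBC",
    "PressureBC",
    "CoupledModel",
    "StaggeredState",
    "StepFailure",
    "run_staggered",
    "crack_angle",
]


class StepFailure(RuntimeError):
    """Newton divergence in the mechanics pass; the driver cuts the step."""


@dataclass
class SolverSettings:
    """Numerical controls of the staggered solver.

    dt / dt_min follow the published protocol (1e-2 reduced to 1e-4 on
    instability).  ``grad_factor`` multiplies Div(L grad d) in the evolution
    equation: 1/2 for the superposed two-mechanism law, 1 for the pure
    crack-surface Euler-Lagrange operator (profile studies).  ``g_floor`` is
    a small residual stiffness keeping fully broken elements invertible.
    """

    dt: float = 1e-2
    dt_min: float = 1e-4
    newton_tol: float = 1e-7
    newton_max_iter: int = 15
    grad_factor: float = 0.5
    g_floor: float = 1e-7
    degrade_compressed_volume: bool = False
    check_mesh_rule: bool = True


@dataclass
class DirichletBC:
    """Prescribed displacement component on a node set.

    ``value(t, X)`` receives the time and the (k, dim) coordinates of the
    nodes and returns a scalar or a (k,) array of prescribed values.
    """

    nodes: np.ndarray
    comp: int
    value: object  # callable(t, X) -> scalar | (k,)


@dataclass
class PressureBC:
    """Follower pressure on a facet set, positive = pushing on the surface
    away from the tube axis (lumen inflation).  ``value(t)`` in kPa."""

    facets: np.ndarray
    value: object  # callable(t) -> float


@dataclass
class StaggeredState:
    """Converged fields at one pseudo-time instant."""

    t: float
    u: np.ndarray      # (nn, dim)
    d: np.ndarray      # (nn,)
    H: np.ndarray      # (ne, nqp) history field at quadrature points

    def copy(self) -> "StaggeredState":
        return StaggeredState(self.t, self.u.copy(), self.d.copy(), self.H.copy())

    def save(self, path) -> None:
        """Checkpoint (binary npz, history keyed by quadrature point) so a
        saw-tooth protocol can be restarted mid-way."""
        np.savez_compressed(path, t=self.t, u=self.u, d=self.d, H=self.H)

    @classmethod
    def load(cls, path) -> "StaggeredState":
        with np.load(path) as z:
            return cls(t=float(z["t"]), u=z["u"], d=z["d"], H=z["H"])


# quadrature / shape functions ------------------------------------------------
_GP = 1.0 / np.sqrt(3.0)
_QUAD_QP = np.array([[-_GP, -_GP], [_GP, -_GP], [_GP, _GP], [-_GP, _GP]])


def _quad_shape(xi):
    s, t = xi
    N = 0.25 * np.array([(1 - s) * (1 - t), (1 + s) * (1 - t),
                         (1 + s) * (1 + t), (1 - s) * (1 + t)])
    dN = 0.25 * np.array([
        [-(1 - t), -(1 - s)],
        [(1 - t), -(1 + s)],
        [(1 + t), (1 + s)],
        [-(1 + t), (1 - s)],
    ])
    return N, dN


class CoupledModel:
    """Mesh + per-region materials + boundary conditions.

    ``materials`` maps each region tag to a (MaterialParams,
    PhaseFieldParams) pair; ``frames`` carries per-element fiber directions
    (a batched :class:`FiberFrame` of shape (ne, 3), or a single frame
    shared by all elements, or None for an isotropic solid).
    """

    def __init__(self, mesh: Mesh, materials: dict, frames: FiberFrame | None = None,
                 settings: SolverSettings | None = None):
        self.mesh = mesh
        self.materials = materials
        self.settings = settings or SolverSettings()
        self.dirichlet: list[DirichletBC] = []
        self.pressure: list[PressureBC] = []

        self.dim = mesh.dim
        self.nn = mesh.n_nodes
        self.ne = mesh.n_elements
        self.ndof = self.nn * self.dim
        conn = mesh.elements

        # broadcast frames to per-element arrays
        if frames is None:
            M = np.zeros((self.ne, 3))
            M[:, 0] = 1.0
            self._frames = FiberFrame(M=M)  # direction irrelevant when k1 = 0
        else:
            M = np.broadcast_to(np.atleast_2d(frames.M), (self.ne, 3)).copy()
            Mp = (np.broadcast_to(np.atleast_2d(frames.Mp), (self.ne, 3)).copy()
                  if frames.Mp is not None else None)
            self._frames = FiberFrame(M=M, Mp=Mp)

        # quadrature data
        X = mesh.nodes[conn]  # (ne, 4, dim)
        if mesh.cell_type == "quad":
            self.nqp = 4
            N_list, dN_list = zip(*(_quad_shape(xi) for xi in _QUAD_QP))
            self.N = np.asarray(N_list)                  # (nqp, 4)
            dN_ref = np.asarray(dN_list)                 # (nqp, 4, 2)
            Jac = np.einsum("qam,ean->eqmn", dN_ref, X)  # dX/dxi transposed pairing
            detJ = np.linalg.det(Jac)
            if np.any(detJ <= 0):
                bad = int(np.argwhere(detJ <= 0)[0][0])
                raise ValueError(f"non-positive Jacobian in element {bad}")
            Jinv = np.linalg.inv(Jac)
            self.gradN = np.einsum("eqnm,qam->eqan", Jinv, dN_ref)  # (ne,nqp,4,dim)
            self.wdetJ = detJ  # unit quadrature weights
        elif mesh.cell_type == "tet":
            self.nqp = 1
            self.N = np.full((1, 4), 0.25)
            E = X[:, 1:] - X[:, :1]  # (ne, 3, 3) edge matrix rows
            vol6 = np.linalg.det(E)
            if np.any(vol6 <= 0):
                bad = int(np.argwhere(vol6 <= 0)[0][0])
                raise ValueError(f"non-positive Jacobian in element {bad}")
            Einv = np.linalg.inv(E)
            g = np.swapaxes(Einv, -1, -2)  # gradients of N1..N3
            g0 = -g.sum(axis=-2, keepdims=True)
            self.gradN = np.concatenate([g0, g], axis=-2)[:, None]  # (ne,1,4,3)
            self.vol = vol6 / 6.0
            self.wdetJ = self.vol[:, None]
        else:  # pragma: no cover
            raise ValueError(mesh.cell_type)

        # per-region element groups
        self.groups = [(int(tag), np.flatnonzero(mesh.region == tag)) for tag in np.unique(mesh.region)]
        for tag, _ in self.groups:
            if tag not in materials:
                raise KeyError(f"no material assigned to region tag {tag}")

        # per-element structure tensor (full L, dim x dim block used)
        self._L = np.empty((self.ne, self.dim, self.dim))
        for tag, idx in self.groups:
            _, pf = materials[tag]
            fr = FiberFrame(M=self._frames.M[idx],
                           Mp=None if self._frames.Mp is None else self._frames.Mp[idx])
            L = pfm.structure_tensor(pf, fr)
            self._L[idx] = L[..., : self.dim, : self.dim]

        if self.settings.check_mesh_rule:
            h = self._min_edge()
            for tag, _ in self.groups:
                l = materials[tag][1].l
                if l <= 2.0 * h:
                    warnings.warn(
                        f"length scale l = {l:.4g} does not satisfy l > 2h "
                        f"(h = {h:.4g}); the diffusive crack surface is under-resolved",
                        stacklevel=2,
                    )
                    break

        # assembly index maps
        edof = (conn[..., None] * self.dim + np.arange(self.dim)).reshape(self.ne, -1)
        self._edof = edof
        npe = edof.shape[1]
        self._Krows = np.repeat(edof, npe, axis=1).ravel()
        self._Kcols = np.tile(edof, (1, npe)).ravel()
        self._drows = np.repeat(conn, 4, axis=1).ravel()
        self._dcols = np.tile(conn, (1, 4)).ravel()

    # ------------------------------------------------------------------ util
    def _min_edge(self) -> float:
        conn = self.mesh.elements
        X = self.mesh.nodes
        if self.mesh.cell_type == "quad":
            pairs = [(0, 1), (1, 2), (2, 3), (3, 0)]
        else:
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        h = np.inf
        for a, b in pairs:
            h = min(h, float(np.min(np.linalg.norm(X[conn[:, a]] - X[conn[:, b]], axis=1))))
        return h

    def _d_max_mech(self, pf: PhaseFieldParams) -> float:
        """Largest damage seen by the mechanics pass: keeps g >= g_floor."""
        if self.settings.g_floor <= 0:
            return 1.0
        return 1.0 - self.settings.g_floor ** (1.0 / min(pf.a_iso, pf.a_ani))

    def _deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F (ne, nqp, 3, 3) from nodal displacements, plane strain in 2-D."""
        ue = u[self.mesh.elements]  # (ne, 4, dim)
        F = np.einsum("eai,eqaJ->eqiJ", ue, self.gradN)
        F3 = np.broadcast_to(np.eye(3), (self.ne, self.nqp, 3, 3)).copy()
        F3[..., : self.dim, : self.dim] += F
        return F3

    def _group_frame(self, idx) -> FiberFrame:
        return FiberFrame(
            M=self._frames.M[idx, None, :],
            Mp=None if self._frames.Mp is None else self._frames.Mp[idx, None, :],
        )

    # ------------------------------------------------------- mechanics pass
    def assemble_mechanics(self, u: np.ndarray, d: np.ndarray, t: float):
        """Global residual and consistent tangent at displacements ``u`` and
        frozen nodal phase field ``d``.  Returns (R, K, f_ext)."""
        F = self._deformation_gradients(u)
        d_qp = np.einsum("qa,ea->eq", self.N, d[self.mesh.elements])
        dim = self.dim

        Pg = np.zeros((self.ne, self.nqp, dim, dim))
        Ag = np.zeros((self.ne, self.nqp, dim, dim, dim, dim))
        for tag, idx in self.groups:
            mat, pf = self.materials[tag]
            fr = self._group_frame(idx)
            st = co.compute_kinematics(F[idx], fr)
            dg = np.clip(d_qp[idx], 0.0, self._d_max_mech(pf))
            dcv = self.settings.degrade_compressed_volume
            P = co.first_piola_stress(st, dg, mat, pf.a_iso, pf.a_ani,
                                      degrade_compressed_volume=dcv)
            A = co.first_piola_tangent(st, dg, mat, pf.a_iso, pf.a_ani,
                                       degrade_compressed_volume=dcv)
            Pg[idx] = P[..., :dim, :dim]
            Ag[idx] = A[..., :dim, :dim, :dim, :dim]

        Re = np.einsum("eq,eqaJ,eqiJ->eai", self.wdetJ, self.gradN, Pg)
        Ke = np.einsum("eq,eqaJ,eqiJkL,eqbL->eaibk", self.wdetJ, self.gradN, Ag, self.gradN)

        R = np.zeros(self.ndof)
        np.add.at(R, self._edof.ravel(), Re.reshape(self.ne, -1).ravel())
        K = sp.coo_matrix(
            (Ke.reshape(self.ne, -1).ravel(), (self._Krows, self._Kcols)),
            shape=(self.ndof, self.ndof),
        ).tocsr()

        f_ext = np.zeros(self.ndof)
        for bc in self.pressure:
            p = float(bc.value(t))
            if p == 0.0:
                continue
            fe, Ke_p, fdof = self._pressure_load(u, bc.facets, p)
            np.add.at(f_ext, fdof.ravel(), fe.ravel())
            nfd = fdof.shape[1]
            rows = np.repeat(fdof, nfd, axis=1).ravel()
            cols = np.tile(fdof, (1, nfd)).ravel()
            K = K - sp.coo_matrix((Ke_p.reshape(len(fdof), -1).ravel(), (rows, cols)),
                                  shape=(self.ndof, self.ndof)).tocsr()
        return R - f_ext, K, f_ext

    def _pressure_load(self, u, facets, p):
        """Consistent follower-pressure nodal forces and load stiffness.

        Returns (fe (nf, k*dim), dfe/dx (nf, k*dim, k*dim), facet dofs).
        The facet orientation is chosen radially outward from the z-axis
        (2-D: outward from the domain centroid) once, in the reference
        configuration.
        """
        X = self.mesh.nodes[facets]
        x = X + u[facets]
        if self.dim == 3:
            a_ref = 0.5 * np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0])
            cen = X.mean(axis=1)
            out = np.column_stack([cen[:, 0], cen[:, 1], np.zeros(len(cen))])
            sign = np.where(np.einsum("fi,fi->f", a_ref, out) >= 0, 1.0, -1.0)
            e21 = x[:, 1] - x[:, 0]
            e31 = x[:, 2] - x[:, 0]
            a = 0.5 * np.cross(e21, e31) * sign[:, None]
            fe = np.repeat((p / 3.0) * a, 3, axis=0).reshape(len(facets), 3, 3)
            # d a / d x_m : a = 0.5 (x2 - x1) x (x3 - x1)
            def skew(v):
                z = np.zeros(len(v))
                return np.stack([
                    np.stack([z, -v[:, 2], v[:, 1]], axis=-1),
                    np.stack([v[:, 2], z, -v[:, 0]], axis=-1),
                    np.stack([-v[:, 1], v[:, 0], z], axis=-1),
                ], axis=-2)
            S21, S31 = skew(e21), skew(e31)
            da = np.zeros((len(facets), 3, 3, 3))  # (f, i, m_node, j)
            da[:, :, 0, :] = 0.5 * (S31 - S21)
            da[:, :, 1, :] = -0.5 * S31
            da[:, :, 2, :] = 0.5 * S21
            da *= sign[:, None, None, None]
            # nodal force n gets (p/3) a for each of the 3 nodes
            Ke = np.zeros((len(facets), 3, 3, 3, 3))  # (f, n, i, m, j)
            for n in range(3):
                Ke[:, n] = (p / 3.0) * da
            fe = fe.reshape(len(facets), 9)
            Ke = Ke.reshape(len(facets), 9, 9)
        else:
            cen_dom = self.mesh.nodes.mean(axis=0)
            t_ref = X[:, 1] - X[:, 0]
            n_ref = np.column_stack([t_ref[:, 1], -t_ref[:, 0]])
            out = X.mean(axis=1) - cen_dom
            sign = np.where(np.einsum("fi,fi->f", n_ref, out) >= 0, 1.0, -1.0)
            tv = x[:, 1] - x[:, 0]
            a = np.column_stack([tv[:, 1], -tv[:, 0]]) * sign[:, None]
            fe = np.repeat((p / 2.0) * a, 2, axis=0).reshape(len(facets), 2, 2)
            R90 = np.array([[0.0, 1.0], [-1.0, 0.0]])
            da = np.zeros((len(facets), 2, 2, 2))
            da[:, :, 0, :] = -R90
            da[:, :, 1, :] = R90
            da *= sign[:, None, None, None]
            Ke = np.zeros((len(facets), 2, 2, 2, 2))
            for n in range(2):
                Ke[:, n] = (p / 2.0) * da
            fe = fe.reshape(len(facets), 4)
            Ke = Ke.reshape(len(facets), 4, 4)
        fdof = (facets[..., None] * self.dim + np.arange(self.dim)).reshape(len(facets), -1)
        return fe, Ke, fdof

    def _apply_dirichlet(self, u: np.ndarray, t: float) -> np.ndarray:
        fixed = np.zeros(self.ndof, dtype=bool)
        for bc in self.dirichlet:
            vals = bc.value(t, self.mesh.nodes[bc.nodes])
            u[bc.nodes, bc.comp] = vals
            fixed[bc.nodes * self.dim + bc.comp] = True
        return fixed

    def _try_assemble(self, u, d, t):
        """Assembly with inadmissible trial states mapped to an infinite
        residual so the line search can back off instead of aborting."""
        try:
            R, K, f_ext = self.assemble_mechanics(u, d, t)
        except (co.InvalidDeformationError, OverflowError):
            return None, None, None, np.inf
        return R, K, f_ext, float(np.linalg.norm(R))

    def solve_mechanics(self, state: StaggeredState, t: float):
        """Newton iteration at frozen phase field with backtracking line
        search on the residual norm; returns (u, iters, R, history)."""
        s = self.settings
        u = state.u.copy()
        fixed = self._apply_dirichlet(u, t)
        free = ~fixed
        R, K, f_ext, _ = self._try_assemble(u, state.d, t)
        if R is None:
            raise StepFailure(f"inadmissible state after boundary update at t = {t:.6g}")
        rnorm = float(np.linalg.norm(R[free]))
        ref = max(rnorm, float(np.linalg.norm(f_ext)), 1e-10)
        history = [rnorm]
        for it in range(s.newton_max_iter + 1):
            if not np.isfinite(rnorm):
                raise StepFailure(f"non-finite residual at t = {t:.6g}")
            if rnorm <= s.newton_tol * ref or rnorm < 1e-12:
                return u, it, R, history
            if it == s.newton_max_iter:
                break
            du = spla.spsolve(K[free][:, free].tocsc(), -R[free])
            if not np.all(np.isfinite(du)):
                raise StepFailure(f"singular tangent at t = {t:.6g}")
            accepted = False
            alpha = 1.0
            for _ in range(6):
                u_try = u.copy()
                u_try.reshape(-1)[free] += alpha * du
                R2, K2, f2, _ = self._try_assemble(u_try, state.d, t)
                r2 = np.inf if R2 is None else float(np.linalg.norm(R2[free]))
                if np.isfinite(r2) and (r2 < rnorm or alpha < 1.0 and r2 < 10 * rnorm):
                    u, R, K, rnorm = u_try, R2, K2, r2
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                raise StepFailure(
                    f"line search stalled at t = {t:.6g} (residual {rnorm:.3g})")
            history.append(rnorm)
        raise StepFailure(
            f"Newton did not converge at t = {t:.6g} "
            f"(residual {history[-1]:.3g} vs ref {ref:.3g})"
        )

    # ------------------------------------------------------- history update
    def update_history(self, u: np.ndarray, H: np.ndarray) -> np.ndarray:
        """Quadrature-point history H <- max(H, <Hbar - 1>) from effective
        (undegraded) energies at the converged displacements."""
        F = self._deformation_gradients(u)
        Hnew = H.copy()
        for tag, idx in self.groups:
            mat, pf = self.materials[tag]
            st = co.compute_kinematics(F[idx], self._group_frame(idx))
            _, _, hbar = pfm.crack_sources(co.psi0_iso(st, mat), co.psi0_ani(st, mat), pf)
            Hnew[idx] = pfm.update_history(H[idx], hbar)
        return Hnew

    # ---------------------------------------------------- phase-field solve
    def solve_phasefield(self, H: np.ndarray, d_n: np.ndarray, dt: float,
                         d_dirichlet=None, grad_factor: float | None = None) -> np.ndarray:
        """One SPD linear solve for the nodal phase field.

        Weak form of  eta (d - d_n)/dt + (1 + H) d - H = gf * Div(L grad d)
        with the natural boundary condition L grad d . N = 0; ``gf`` defaults
        to the solver setting (1/2 for the superposed evolution law).
        """
        gf = self.settings.grad_factor if grad_factor is None else grad_factor
        conn = self.mesh.elements
        eta_dt = np.zeros(self.ne)
        for tag, idx in self.groups:
            eta_dt[idx] = self.materials[tag][1].eta / dt

        if self.mesh.cell_type == "tet":
            coef = 1.0 + H[:, 0] + eta_dt
            m_unit = (np.ones((4, 4)) + np.eye(4)) / 20.0
            Me = coef[:, None, None] * self.vol[:, None, None] * m_unit
            Kgrad = np.einsum("e,eqaI,eIJ,eqbJ->eab", gf * self.vol,
                              self.gradN[:, :, :, :], self._L, self.gradN[:, :, :, :])
            rhs_e = (H[:, 0] * self.vol / 4.0)[:, None] * np.ones(4)
            rhs_e = rhs_e + np.einsum("e,eab,eb->ea", eta_dt, self.vol[:, None, None] * m_unit,
                                      d_n[conn])
            Ke = Me + Kgrad
        else:
            coef_q = 1.0 + H + eta_dt[:, None]  # (ne, nqp)
            NN = np.einsum("qa,qb->qab", self.N, self.N)
            Me = np.einsum("eq,qab->eab", self.wdetJ * coef_q, NN)
            Kgrad = np.einsum("eq,eqaI,eIJ,eqbJ->eab", gf * self.wdetJ, self.gradN,
                              self._L, self.gradN)
            dn_qp = np.einsum("qa,ea->eq", self.N, d_n[conn])
            rhs_e = np.einsum("eq,qa->ea", self.wdetJ * (H + eta_dt[:, None] * dn_qp), self.N)
            Ke = Me + Kgrad

        A = sp.coo_matrix((Ke.ravel(), (self._drows, self._dcols)),
                          shape=(self.nn, self.nn)).tocsr()
        b = np.zeros(self.nn)
        np.add.at(b, conn.ravel(), rhs_e.ravel())

        if d_dirichlet:
            fixed = np.zeros(self.nn, dtype=bool)
            dvals = np.zeros(self.nn)
            for nodes, val in d_dirichlet:
                fixed[nodes] = True
                dvals[nodes] = val
            free = ~fixed
            b_free = b[free] - A[free][:, fixed] @ dvals[fixed]
            d = dvals.copy()
            d[free] = spla.spsolve(A[free][:, free].tocsc(), b_free)
        else:
            d = spla.spsolve(A.tocsc(), b)
        return d

    # --------------------------------------------------------- one-pass step
    def staggered_step(self, state: StaggeredState, t: float, dt: float):
        """ALGO_C after ALGO_M: mechanics at frozen d, history update, one
        linear phase-field solve, projection onto [d_n, 1]."""
        u, iters, R, _ = self.solve_mechanics(state, t)
        H = self.update_history(u, state.H)
        d = self.solve_phasefield(H, state.d, dt)
        d = np.clip(d, state.d, 1.0)
        new = StaggeredState(t=t, u=u, d=d, H=H)
        return new, {"newton_iters": iters, "residual": R}

    # ------------------------------------------------------------- reactions
    def reaction_force(self, state: StaggeredState, node_set: str, comp: int) -> float:
        """Sum of residual contributions at the constrained nodes of a named
        node set along direction ``comp`` (mN)."""
        if node_set not in self.mesh.node_sets:
            raise KeyError(
                f"unknown node set {node_set!r}; available: {sorted(self.mesh.node_sets)}"
            )
        R, _, _ = self.assemble_mechanics(state.u, state.d, state.t)
        nodes = self.mesh.node_sets[node_set]
        return float(R[nodes * self.dim + comp].sum())

    def cauchy_stresses(self, state: StaggeredState) -> np.ndarray:
        """Per-element quadrature-averaged Cauchy stress sigma = tau / J (kPa)."""
        F = self._deformation_gradients(state.u)
        d_qp = np.einsum("qa,ea->eq", self.N, state.d[self.mesh.elements])
        sig = np.zeros((self.ne, 3, 3))
        for tag, idx in self.groups:
            mat, pf = self.materials[tag]
            st = co.compute_kinematics(F[idx], self._group_frame(idx))
            dg = np.clip(d_qp[idx], 0.0, self._d_max_mech(pf))
            tau = co.kirchhoff_stress(
                st, dg, mat, pf.a_iso, pf.a_ani,
                degrade_compressed_volume=self.settings.degrade_compressed_volume)
            sig[idx] = (tau / st.J[..., None, None]).mean(axis=1)
        return sig

    def initial_state(self) -> StaggeredState:
        return StaggeredState(
            t=0.0,
            u=np.zeros((self.nn, self.dim)),
            d=np.zeros(self.nn),
            H=np.zeros((self.ne, self.nqp)),
        )


def run_staggered(model: CoupledModel, t_end: float, state: StaggeredState | None = None,
                  snapshot_times=(), callback=None, stop_when=None):
    """Drive the staggered scheme from ``state`` to ``t_end``.

    Pseudo-time steps of ``settings.dt`` are halved on Newton failure down to
    ``settings.dt_min``; the run then stops and reports the last converged
    state.  ``snapshot_times`` are hit exactly; ``callback(state, log_row)``
    runs after each converged step; ``stop_when(state)`` can end the run
    early.  Returns (final state, log rows, snapshots dict, completed flag).
    """
    s = model.settings
    state = state.copy() if state is not None else model.initial_state()
    snap_left = sorted(t for t in snapshot_times if t > state.t + 1e-12)
    snapshots = {}
    log = []
    dt = s.dt
    completed = True
    while state.t < t_end - 1e-12:
        target = state.t + dt
        if snap_left:
            target = min(target, snap_left[0])
        target = min(target, t_end)
        try:
            new, info = model.staggered_step(state, target, target - state.t)
        except StepFailure:
            if dt / 2.0 < s.dt_min:
                completed = False
                break
            dt /= 2.0
            continue
        state = new
        row = {
            "t": state.t,
            "dt": target - (log[-1]["t"] if log else 0.0),
            "newton_iters": info["newton_iters"],
            "max_d": float(state.d.max()),
        }
        log.append(row)
        if callback is not None:
            callback(state, row)
        if snap_left and abs(state.t - snap_left[0]) < 1e-12:
            snapshots[snap_left.pop(0)] = state.copy()
        if stop_when is not None and stop_when(state):
            break
        dt = min(dt * 1.5, s.dt)
    return state, log, snapshots, completed


def crack_angle(mesh: Mesh, d: np.ndarray, threshold: float = 0.8,
                x_min: float | None = None):
    """Crack path angle from the thresholded phase-field point cloud.

    Element centroids with mean nodal d >= threshold (optionally restricted
    to x > x_min, e.g. beyond the notch tip) are fit with a least-squares
    line via their principal direction; the angle to the horizontal axis is
    returned in degrees in (-90, 90].  Returns None when the thresholded set
    is empty (no crack), which is distinct from an angle of 0.
    """
    d_el = d[mesh.elements].mean(axis=1)
    cent = mesh.centroids()
    mask = d_el >= threshold
    if x_min is not None:
        mask &= cent[:, 0] > x_min
    pts = cent[mask][:, :2]
    if len(pts) < 2:
        return None
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    ang = np.degrees(np.arctan2(v[1], v[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)
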