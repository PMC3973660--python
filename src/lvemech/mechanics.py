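"""Quasi-static finite elasticity of the ventricular wall.

Passive myocardium follows the exponential (Fung/Usyk-type) strain-energy
function

    W = C0/2 * (exp(Q) - 1) + kappa * (J ln J - J + 1),
    Q  = b_ff E_ff^2 + b_ss E_ss^2 + b_nn E_nn^2
       + b_fs (E_fs^2 + E_sf^2) + b_fn (E_fn^2 + E_nf^2)
       + b_sn (E_sn^2 + E_ns^2),

with E the Green-Lagrange strain expressed in the local fibre/sheet/normal
basis and J = det F.  The volumetric term is a convex penalty that keeps
the tissue nearly incompressible; active contraction adds a rank-one
second Piola-Kirchhoff stress T_a f (x) f along the reference fibre.

Discretization: 10-node quadratic tetrahedra (straight edges, affine
geometry map), 4-point quadrature, total-Lagrangian Newton iterations with
an analytic consistent tangent.  The endocardial blood pressure enters as a
follower load through the potential -p * V_cavity(u), whose exact gradient
and Hessian over the triangulated cavity closure give the deformation-
dependent traction -p J F^-T N per reference area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .geometry import scale_mesh
from .mesh import LVMesh, cavity_closure, surface_triangles
from .microstructure import StructureField

logger = logging.getLogger(__name__)

_QP_A = 0.5854101966249685
_QP_B = 0.13819660112501053
# barycentric quadrature points (degree 2, 4 points, weight 1/4 each)
_QPOINTS = np.array([
    [_QP_A, _QP_B, _QP_B, _QP_B],
    [_QP_B, _QP_A, _QP_B, _QP_B],
    [_QP_B, _QP_B, _QP_A, _QP_B],
    [_QP_B, _QP_B, _QP_B, _QP_A],
])
_CENTROID = np.full((1, 4), 0.25)


@dataclass(frozen=True)
class MaterialLaw:
    """Exponential orthotropic law: C0 (kPa), exponents b_*, penalty kappa."""

    C0: float = 0.88
    b_ff: float = 6.0
    b_ss: float = 7.0
    b_nn: float = 3.0
    b_fs: float = 12.0
    b_fn: float = 3.0
    b_sn: float = 3.0
    kappa: float = 100.0
    symmetry: str = "orthotropic"

    def __post_init__(self):
        if min(self.C0, self.b_ff, self.b_ss, self.b_nn, self.b_fs,
               self.b_fn, self.b_sn, self.kappa) <= 0:
            raise ValueError("all material parameters must be positive")
        if self.symmetry == "transverse_isotropic":
            if not (np.isclose(self.b_ss, self.b_nn)
                    and np.isclose(self.b_fs, self.b_fn)):
                raise ValueError("transverse isotropy requires b_ss = b_nn "
                                 "and b_fs = b_fn")

    @classmethod
    def orthotropic(cls, C0: float = 0.88, kappa: float = 100.0) -> "MaterialLaw":
        return cls(C0=C0, b_ff=6.0, b_ss=7.0, b_nn=3.0, b_fs=12.0,
                   b_fn=3.0, b_sn=3.0, kappa=kappa, symmetry="orthotropic")

    @classmethod
    def transverse_isotropic(cls, C0: float = 0.88,
                             kappa: float = 100.0) -> "MaterialLaw":
        return cls(C0=C0, b_ff=6.0, b_ss=4.3, b_nn=4.3, b_fs=7.5,
                   b_fn=7.5, b_sn=4.3, kappa=kappa,
                   symmetry="transverse_isotropic")

    @property
    def b_matrix(self) -> np.ndarray:
        return np.array([
            [self.b_ff, self.b_fs, self.b_fn],
            [self.b_fs, self.b_ss, self.b_sn],
            [self.b_fn, self.b_sn, self.b_nn],
        ])


@dataclass
class BoundarySpec:
    """Base constraint (long-axis displacement fixed, in-plane free) and
    endocardial cavity pressure (kPa; positive inflates)."""

    pressure: float = 0.0
    fix_base_long_axis: bool = True
    pin_rigid_motion: bool = True
    # extra prescribed dofs: list of (node_id, component, value)
    prescribed: list = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.pressure):
            raise ValueError("pressure must be finite")


@dataclass
class MechState:
    """Converged mechanical state with per-element centroid tensors."""

    u: np.ndarray  # (n, 3) nodal displacements
    F: np.ndarray  # (ne, 3, 3) at element centroids
    E: np.ndarray  # (ne, 3, 3) Green-Lagrange strain (global basis)
    J: np.ndarray  # (ne,)
    S_p: np.ndarray
    S_a: np.ndarray
    S: np.ndarray
    cavity_volume: Optional[float] = None
    newton_iterations: int = 0


# ---------------------------------------------------------------------------
# pointwise constitutive operations (leading dims broadcast)

def green_strain(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I) / 2; requires det F > 0."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient has non-positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    return 0.5 * (C - np.eye(3))


def _jacobian_from_strain(E: np.ndarray) -> np.ndarray:
    C = 2.0 * np.asarray(E, dtype=float) + np.eye(3)
    detC = np.linalg.det(C)
    if np.any(detC <= 0):
        raise ValueError("strain state implies non-positive volume ratio")
    return np.sqrt(detC)


def strain_energy(E: np.ndarray, J=None, law: MaterialLaw = None) -> np.ndarray:
    """Energy density (kPa) for strain E in the fibre basis.

    If J is omitted it is derived from E (the penalty formulation carries no
    independent volumetric variable).
    """
    law = law or MaterialLaw.orthotropic()
    E = np.asarray(E, dtype=float)
    if J is None:
        J = _jacobian_from_strain(E)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("J must be positive")
    B = law.b_matrix
    Q = np.einsum("ij,...ij->...", B, E ** 2)
    return (law.C0 / 2.0) * (np.exp(Q) - 1.0) \
        + law.kappa * (J * np.log(J) - J + 1.0)


def passive_stress(E: np.ndarray, law: MaterialLaw = None, J=None) -> np.ndarray:
    """Second Piola-Kirchhoff stress dW/dE, in the same basis as E."""
    law = law or MaterialLaw.orthotropic()
    E = np.asarray(E, dtype=float)
    if J is None:
        J = _jacobian_from_strain(E)
    J = np.asarray(J, dtype=float)
    B = law.b_matrix
    Q = np.einsum("ij,...ij->...", B, E ** 2)
    S_exp = law.C0 * np.exp(Q)[..., None, None] * (B * E)
    C = 2.0 * E + np.eye(3)
    Cinv = np.linalg.inv(C)
    S_vol = law.kappa * (J * np.log(J))[..., None, None] * Cinv
    return S_exp + S_vol


def active_stress(T_a, f: np.ndarray) -> np.ndarray:
    """S_a = T_a f (x) f in the reference fibre basis; T_a >= 0 (kPa)."""
    T_a = np.asarray(T_a, dtype=float)
    if np.any(T_a < 0):
        raise ValueError("active tension must be non-negative")
    f = np.asarray(f, dtype=float)
    return T_a[..., None, None] * np.einsum("...i,...j->...ij", f, f)


# ---------------------------------------------------------------------------
# P2 shape functions

def _shape_gradients_dL(L: np.ndarray) -> np.ndarray:
    """dN/dL for the 10-node tet at barycentric points L: (nq, 10, 4)."""
    nq = len(L)
    dN = np.zeros((nq, 10, 4))
    for a in range(4):
        dN[:, a, a] = 4.0 * L[:, a] - 1.0
    from .mesh import TET10_EDGES
    for e, (i, j) in enumerate(TET10_EDGES):
        dN[:, 4 + e, i] = 4.0 * L[:, j]
        dN[:, 4 + e, j] = 4.0 * L[:, i]
    return dN


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


class QuasiStaticSolver:
    """Newton solver for quasi-static finite elasticity on a quadratic mesh.

    Precomputes quadrature data, fibre rotations and the cavity closure so
    repeated solves (pressure/tension stepping, warm starts) are cheap.
    """

    def __init__(self, mesh: LVMesh, structure: StructureField,
                 law: MaterialLaw, boundary: BoundarySpec,
                 rtol: float = 1e-8, max_newton: int = 25,
                 max_halvings: int = 8):
        if mesh.order != 2:
            raise ValueError("mechanics requires quadratic (order-2) elements")
        if len(structure) != mesh.n_elements:
            raise ValueError("structure field does not match the mesh")
        self.mesh = mesh
        self.law = law
        self.boundary = boundary
        self.rtol = rtol
        self.max_newton = max_newton
        self.max_halvings = max_halvings

        nodes, tets = mesh.nodes, mesh.tets
        x0 = nodes[tets[:, 0]]
        Jg = np.stack([nodes[tets[:, i]] - x0 for i in (1, 2, 3)], axis=2)
        detJ = np.linalg.det(Jg)
        if np.any(detJ <= 0):
            raise ValueError("mesh has non-positively oriented elements")
        Jinv = np.linalg.inv(Jg)
        # dL/dX: rows are gradients of L1..L3; L0 = -sum
        gl = Jinv  # (ne, 3, 3): gl[e, k, :] = dxi_k/dX = dL_{k+1}/dX
        dLdX = np.concatenate([-gl.sum(axis=1, keepdims=True), gl], axis=1)

        def dndx(L):
            dNdL = _shape_gradients_dL(L)  # (nq, 10, 4)
            return np.einsum("qam,emj->eqaj", dNdL, dLdX)

        self.dNdX = dndx(_QPOINTS)          # (ne, 4, 10, 3)
        self.dNdX_c = dndx(_CENTROID)[:, 0]  # (ne, 10, 3)
        self.wdet = np.repeat((np.abs(detJ) / 6.0)[:, None], 4, axis=1) / 4.0
        self.R = structure.rotation_matrices()  # columns f, s, n
        self.f_vec = structure.f
        self.B = law.b_matrix

        # scatter indices for the (ne, 10, 3, 10, 3) element stiffness
        dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 30)
        self._rows = np.repeat(dof, 30, axis=1).ravel()
        self._cols = np.tile(dof, (1, 30)).ravel()
        self._fdof = dof  # (ne, 30)
        self.ndof = 3 * mesh.n_nodes

        # Dirichlet constraints
        fixed = {}
        if boundary.fix_base_long_axis and "base" in mesh.surfaces:
            base_nodes = self._base_nodes()
            for nd in base_nodes:
                fixed[3 * nd + 2] = 0.0
            if boundary.pin_rigid_motion:
                pts = nodes[base_nodes]
                n_px = base_nodes[np.argmax(pts[:, 0])]
                n_py = base_nodes[np.argmax(pts[:, 1])]
                fixed[3 * n_px + 0] = 0.0
                fixed[3 * n_px + 1] = 0.0
                fixed[3 * n_py + 0] = 0.0
        for (nd, comp, val) in boundary.prescribed:
            fixed[3 * nd + comp] = float(val)
        if not fixed:
            raise ValueError("boundary specification constrains no dofs")
        self.fixed_dofs = np.array(sorted(fixed), dtype=np.int64)
        self.fixed_vals = np.array([fixed[d] for d in self.fixed_dofs])
        self.free = np.ones(self.ndof, dtype=bool)
        self.free[self.fixed_dofs] = False

        # cavity closure for the follower pressure load
        self._has_cavity = "endocardium" in mesh.surfaces
        if self._has_cavity:
            tris, rim, sign = cavity_closure(mesh)
            self.cav_tris = tris
            self.cav_rim = rim
            self.cav_sign = sign
            self.cap_apex = nodes[np.unique(rim)].mean(axis=0) if len(rim) \
                else np.zeros(3)
        elif boundary.pressure != 0.0:
            raise ValueError("pressure load requires a tagged endocardium")

    def _base_nodes(self) -> np.ndarray:
        faces = self.mesh.surfaces["base"]
        corners = np.unique(faces)
        if self.mesh.order == 2:
            from .mesh import edge_midpoint_map
            mids = edge_midpoint_map(self.mesh)
            cs = set(corners.tolist())
            extra = [m for (a, b), m in mids.items() if a in cs and b in cs]
            # keep only midside nodes geometrically on the base plane
            zb = self.mesh.nodes[corners][:, 2].mean()
            tol = 1e-9 * max(1.0, abs(zb))
            extra = [m for m in extra
                     if abs(self.mesh.nodes[m, 2] - zb) < 1e-8 + tol]
            corners = np.unique(np.concatenate([corners, np.array(extra, dtype=np.int64)])) \
                if extra else corners
        return corners

    # -- cavity volume -----------------------------------------------------

    def cavity_volume(self, u: Optional[np.ndarray] = None) -> float:
        if not self._has_cavity:
            raise ValueError("mesh has no cavity")
        x = self.mesh.nodes if u is None else self.mesh.nodes + u
        return self.cav_sign * self._signed_volume(x)

    def _signed_volume(self, x: np.ndarray) -> float:
        t = self.cav_tris
        a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
        v = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
        if len(self.cav_rim):
            p, q = x[self.cav_rim[:, 1]], x[self.cav_rim[:, 0]]
            apx = np.broadcast_to(self.cap_apex, p.shape)
            v += np.einsum("ij,ij->i", p, np.cross(q, apx)).sum() / 6.0
        return v

    def _volume_gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        t = self.cav_tris
        a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
        np.add.at(g, t[:, 0], np.cross(b, c) / 6.0)
        np.add.at(g, t[:, 1], np.cross(c, a) / 6.0)
        np.add.at(g, t[:, 2], np.cross(a, b) / 6.0)
        if len(self.cav_rim):
            p, q = x[self.cav_rim[:, 1]], x[self.cav_rim[:, 0]]
            apx = np.broadcast_to(self.cap_apex, p.shape)
            np.add.at(g, self.cav_rim[:, 1], np.cross(q, apx) / 6.0)
            np.add.at(g, self.cav_rim[:, 0], np.cross(apx, p) / 6.0)
        return g

    def _volume_hessian(self, x: np.ndarray) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []

        def add_block(ni, nj, M):
            r = (3 * ni[:, None, None] + np.arange(3)[None, :, None])
            c = (3 * nj[:, None, None] + np.arange(3)[None, None, :])
            rows.append(np.broadcast_to(r, M.shape).ravel())
            cols.append(np.broadcast_to(c, M.shape).ravel())
            vals.append(M.ravel())

        t = self.cav_tris
        xa, xb, xc = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]

        def skew_batch(v):
            S = np.zeros((len(v), 3, 3))
            S[:, 0, 1] = -v[:, 2]
            S[:, 0, 2] = v[:, 1]
            S[:, 1, 0] = v[:, 2]
            S[:, 1, 2] = -v[:, 0]
            S[:, 2, 0] = -v[:, 1]
            S[:, 2, 1] = v[:, 0]
            return S

        # d2V/da db = -[c]x / 6 etc. (and transposes for the mirrored block)
        Sc, Sb, Sa = skew_batch(xc) / 6.0, skew_batch(xb) / 6.0, skew_batch(xa) / 6.0
        add_block(t[:, 0], t[:, 1], -Sc)
        add_block(t[:, 1], t[:, 0], Sc.transpose(0, 2, 1) * -1.0)
        add_block(t[:, 0], t[:, 2], Sb)
        add_block(t[:, 2], t[:, 0], Sb.transpose(0, 2, 1))
        add_block(t[:, 1], t[:, 2], -Sa)
        add_block(t[:, 2], t[:, 1], Sa.transpose(0, 2, 1) * -1.0)
        if len(self.cav_rim):
            n1, n0 = self.cav_rim[:, 1], self.cav_rim[:, 0]
            Sapex = np.broadcast_to(_skew(self.cap_apex) / 6.0,
                                    (len(n1), 3, 3))
            add_block(n1, n0, -Sapex)
            add_block(n0, n1, Sapex.transpose(0, 2, 1) * -1.0)
        H = sparse.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof)).tocsr()
        return H

    # -- assembly ----------------------------------------------------------

    def _kinematics(self, u: np.ndarray, dNdX: np.ndarray):
        ue = u[self.mesh.tets]  # (ne, 10, 3)
        return np.einsum("eai,eqaJ->eqiJ", ue, dNdX) + np.eye(3)

    def _stress_and_tangent(self, F: np.ndarray, Ta: Optional[np.ndarray],
                            want_tangent: bool):
        """S (global) and material tangent dS/dE (global) at (ne, nq) points."""
        law, B, R = self.law, self.B, self.R
        C = np.einsum("eqkI,eqkJ->eqIJ", F, F)
        J2 = np.linalg.det(C)
        if np.any(J2 <= 0):
            return None, None, None
        J = np.sqrt(J2)
        E = 0.5 * (C - np.eye(3))
        Eloc = np.einsum("eiI,eqij,ejJ->eqIJ", R, E, R)
        Q = np.einsum("IJ,eqIJ->eq", B, Eloc ** 2)
        expQ = law.C0 * np.exp(Q)
        M = B * Eloc  # elementwise
        Sloc = expQ[..., None, None] * M
        Spas = np.einsum("eiI,eqIJ,ejJ->eqij", R, Sloc, R)
        Cinv = np.linalg.inv(C)
        g = law.kappa * (J * np.log(J))
        Svol = g[..., None, None] * Cinv
        S = Spas + Svol
        if Ta is not None:
            ff = np.einsum("ei,ej->eij", self.f_vec, self.f_vec)
            S = S + Ta[:, None, None, None] * ff[:, None]
        if not want_tangent:
            return S, J, None
        ne, nq = Q.shape
        eye = np.eye(3)
        Isym = 0.5 * (np.einsum("ik,jl->ijkl", eye, eye)
                      + np.einsum("il,jk->ijkl", eye, eye))
        DDloc = expQ[..., None, None, None, None] * (
            B[None, None, :, :, None, None] * Isym[None, None]
            + 2.0 * np.einsum("eqij,eqkl->eqijkl", M, M))
        # rotate to the global basis one index at a time
        DD = np.einsum("eaI,eqIJKL->eqaJKL", R, DDloc, optimize=True)
        DD = np.einsum("ebJ,eqaJKL->eqabKL", R, DD, optimize=True)
        DD = np.einsum("ecK,eqabKL->eqabcL", R, DD, optimize=True)
        DD = np.einsum("edL,eqabcL->eqabcd", R, DD, optimize=True)
        # volumetric tangent: dSvol/dE = 2 dSvol/dC
        lnJ = np.log(J)
        c1 = law.kappa * (lnJ + 1.0) * J
        CiCi = np.einsum("eqij,eqkl->eqijkl", Cinv, Cinv)
        CiI = 0.5 * (np.einsum("eqik,eqjl->eqijkl", Cinv, Cinv)
                     + np.einsum("eqil,eqjk->eqijkl", Cinv, Cinv))
        DD = DD + c1[..., None, None, None, None] * CiCi \
            - 2.0 * g[..., None, None, None, None] * CiI
        return S, J, DD

    def assemble(self, u: np.ndarray, pressure: float,
                 Ta: Optional[np.ndarray], want_tangent: bool):
        """Residual (internal - external) and tangent; None on invalid state."""
        F = self._kinematics(u, self.dNdX)
        S, J, DD = self._stress_and_tangent(F, Ta, want_tangent)
        if S is None:
            return None, None
        P = np.einsum("eqiI,eqIJ->eqiJ", F, S)
        wd = self.wdet
        fe = np.einsum("eq,eqiJ,eqaJ->eai", wd, P, self.dNdX)
        R = np.zeros(self.ndof)
        np.add.at(R, self._fdof, fe.reshape(len(fe), 30))
        x = self.mesh.nodes + u
        if pressure != 0.0:
            g = self.cav_sign * self._volume_gradient(x)
            R -= pressure * g.ravel()
        if not want_tangent:
            return R, None
        A = np.einsum("ik,eqJL->eqiJkL", np.eye(3), S) \
            + np.einsum("eqiI,eqIJML,eqkM->eqiJkL", F, DD, F, optimize=True)
        # K_e[a i b k] = sum_{q J L} w dN_aJ A_iJkL dN_bL, as batched matmuls
        ne, nq = wd.shape
        A2 = A.transpose(0, 1, 3, 2, 4, 5).reshape(ne, nq, 3, 27)
        W1 = np.matmul(self.dNdX, A2)            # (e, q, 10, (i k L))
        W1 = W1.reshape(ne, nq, 10 * 9, 3)
        dNw = self.dNdX * wd[..., None, None]
        W2 = np.matmul(W1, dNw.transpose(0, 1, 3, 2))  # (e, q, (a i k), b)
        Ke = W2.reshape(ne, nq, 10, 3, 3, 10).sum(axis=1)  # (e, a, i, k, b)
        Ke = Ke.transpose(0, 1, 2, 4, 3)         # (e, a, i, b, k)
        K = sparse.coo_matrix(
            (Ke.reshape(len(Ke), -1).ravel(), (self._rows, self._cols)),
            shape=(self.ndof, self.ndof)).tocsr()
        if pressure != 0.0:
            K = K - pressure * self.cav_sign * self._volume_hessian(x)
        return R, K

    # -- Newton ------------------------------------------------------------

    def _newton(self, u: np.ndarray, pressure: float,
                Ta: Optional[np.ndarray]):
        free = self.free
        u = u.copy()
        u.ravel()[self.fixed_dofs] = self.fixed_vals
        scale = None
        with np.errstate(over="ignore", invalid="ignore"):
            R, _ = self.assemble(u, pressure, Ta, want_tangent=False)
        if R is None or not np.all(np.isfinite(R)):
            return None, 0
        for it in range(self.max_newton):
            rnorm = np.linalg.norm(R[free])
            if scale is None:
                scale = max(rnorm, 1e-8)
            if rnorm <= self.rtol * scale or rnorm < 1e-12:
                return u, it
            with np.errstate(over="ignore", invalid="ignore"):
                _, K = self.assemble(u, pressure, Ta, want_tangent=True)
            try:
                du = splu(K[free][:, free].tocsc()).solve(-R[free])
            except RuntimeError:
                return None, it
            if not np.all(np.isfinite(du)):
                return None, it
            # backtracking on the residual norm (exponential stiffening can
            # make the full Newton step overshoot); trials are residual-only
            accepted = False
            alpha = 1.0
            for _ in range(8):
                u_try = u.copy()
                u_try.ravel()[free] += alpha * du
                with np.errstate(over="ignore", invalid="ignore"):
                    R_try, _ = self.assemble(u_try, pressure, Ta,
                                             want_tangent=False)
                if R_try is not None and np.all(np.isfinite(R_try)) and \
                        np.linalg.norm(R_try[free]) < rnorm * (1.0 - 1e-4 * alpha) + 1e-14:
                    u, R = u_try, R_try
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                # accept near-converged states rather than failing outright
                if rnorm <= 1e-4 * scale:
                    logger.warning("Newton stalled at loose tolerance "
                                   "(%.2e rel)", rnorm / scale)
                    return u, it
                return None, it
        if np.linalg.norm(R[free]) <= 1e-4 * scale:
            logger.warning("Newton stopped at loose tolerance (%.2e rel)",
                           np.linalg.norm(R[free]) / scale)
            return u, self.max_newton
        return None, self.max_newton

    def solve(self, pressure: float = 0.0, Ta=None,
              u0: Optional[np.ndarray] = None,
              n_load_steps: int = 1) -> MechState:
        """Solve for equilibrium at the given loads with load stepping.

        ``Ta`` is a per-element active fibre tension (kPa).  Failed Newton
        iterations halve the load increment (up to ``max_halvings``).
        """
        if Ta is not None:
            Ta = np.asarray(Ta, dtype=float)
            if np.any(Ta < 0):
                raise ValueError("active tension must be non-negative")
        u = np.zeros((self.mesh.n_nodes, 3)) if u0 is None else u0.copy()
        lam0, lam = 0.0, 0.0
        step = 1.0 / n_load_steps
        halvings = 0
        total_its = 0
        # warm starts usually let a single step succeed
        while lam < 1.0 - 1e-12:
            lam_try = min(1.0, lam + step)
            Ta_try = None if Ta is None else lam_try * Ta
            unew, its = self._newton(u, lam_try * pressure, Ta_try)
            total_its += its
            if unew is None:
                halvings += 1
                step /= 2.0
                if halvings > self.max_halvings:
                    raise RuntimeError(
                        f"load stepping failed; last converged load fraction "
                        f"{lam:.4f} of (p={pressure}, max Ta="
                        f"{0 if Ta is None else float(np.max(Ta))})")
                continue
            u, lam = unew, lam_try
        return self._state(u, Ta, total_its)

    def _state(self, u: np.ndarray, Ta, its: int) -> MechState:
        ue = u[self.mesh.tets]
        F = np.einsum("eai,eaJ->eiJ", ue, self.dNdX_c) + np.eye(3)
        C = np.einsum("ekI,ekJ->eIJ", F, F)
        J = np.sqrt(np.linalg.det(C))
        E = 0.5 * (C - np.eye(3))
        R = self.R
        Eloc = np.einsum("eiI,eij,ejJ->eIJ", R, E, R)
        Sp_loc = passive_stress(Eloc, self.law)
        Sp = np.einsum("eiI,eIJ,ejJ->eij", R, Sp_loc, R)
        Sa = active_stress(np.zeros(len(F)) if Ta is None else Ta, self.f_vec)
        vol = self.cavity_volume(u) if self._has_cavity else None
        return MechState(u=u, F=F, E=E, J=J, S_p=Sp, S_a=Sa, S=Sp + Sa,
                         cavity_volume=vol, newton_iterations=its)


# ---------------------------------------------------------------------------
# high-level operations

def solve_quasistatic(mesh: LVMesh, structure: StructureField,
                      law: MaterialLaw, boundary: BoundarySpec,
                      Ta=None, n_load_steps: int = 2) -> MechState:
    """One-shot equilibrium solve (see :class:`QuasiStaticSolver`)."""
    solver = QuasiStaticSolver(mesh, structure, law, boundary)
    return solver.solve(pressure=boundary.pressure, Ta=Ta,
                        n_load_steps=n_load_steps)


def inflate(mesh: LVMesh, structure: StructureField, law: MaterialLaw,
            pressure: float, n_load_steps: int = 3,
            solver: Optional[QuasiStaticSolver] = None) -> LVMesh:
    """Passively pressurize the cavity; returns the deformed mesh."""
    if pressure < 0:
        raise ValueError("inflation pressure magnitude must be >= 0")
    if solver is None:
        solver = QuasiStaticSolver(mesh, structure, law,
                                   BoundarySpec(pressure=pressure))
    state = solver.solve(pressure=pressure, n_load_steps=n_load_steps)
    return mesh.copy_with_nodes(mesh.nodes + state.u, provenance="post-P")


def estimate_unloaded(reference: LVMesh, structure: StructureField,
                      law: MaterialLaw, pressure: float,
                      vol_tol: float = 0.02, max_iter: int = 15,
                      s_min: float = 0.5):
    """Find the uniform shrink factor whose passive inflation recovers the
    reference cavity volume.

    Returns (s, pre_P, post_P).  Bisection on the cavity-volume mismatch;
    uniform scaling leaves the transmural coordinate and all frames
    unchanged, so the structure field is reused.
    """
    from .geometry import cavity_volume as _cav
    v_ref = _cav(reference)
    if pressure == 0.0:
        pre = reference.copy_with_nodes(reference.nodes, provenance="pre-P")
        post = reference.copy_with_nodes(reference.nodes, provenance="post-P")
        return 1.0, pre, post

    def post_volume(s):
        m = scale_mesh(reference, s)
        post = inflate(m, structure, law, pressure)
        return _cav(reference, post.nodes), m, post

    s_hi, s_lo = 1.0, None
    v_hi, _, post_hi = post_volume(1.0)
    if v_hi < v_ref:
        raise RuntimeError("inflation decreased cavity volume; check signs")
    s = 1.0
    for s_try in (0.95, 0.9, 0.85, 0.8, 0.7, 0.6, s_min):
        v, m, post = post_volume(s_try)
        if v < v_ref:
            s_lo, v_lo = s_try, v
            break
        s_hi, v_hi = s_try, v
        if abs(v - v_ref) <= vol_tol * v_ref:
            pre = scale_mesh(reference, s_try)
            pre.provenance = "pre-P"
            return s_try, pre, post
    else:
        raise RuntimeError(f"could not bracket the unloaded scale above "
                           f"{s_min}")
    best = (s_hi, v_hi)
    for _ in range(max_iter):
        s = 0.5 * (s_lo + s_hi)
        v, m, post = post_volume(s)
        if abs(v - v_ref) <= vol_tol * v_ref:
            pre = scale_mesh(reference, s)
            pre.provenance = "pre-P"
            return s, pre, post
        if v > v_ref:
            s_hi = s
        else:
            s_lo = s
    raise RuntimeError(f"unloaded-geometry bisection did not reach "
                       f"{vol_tol:.0%} volume agreement in {max_iter} "
                       f"iterations (last s={s:.4f})")
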