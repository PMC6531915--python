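"""Anisotropic diffusion operator on a hexahedral tissue grid.

Trilinear hexahedral finite elements with 2x2x2 Gauss quadrature and a
lumped mass matrix.  Scar elements are excluded from the assembly, which
realizes the internal no-flux boundary at the scar interface; the outer
boundary is no-flux by construction (natural boundary condition).  The
conductivity tensor per element is sigma_L f f^T + sigma_T (I - f f^T)
with f the element fiber unit vector.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..substrate.grid import TissueGrid

_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [1, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
    ]
)


def _gauss_gradients(dx: float) -> np.ndarray:
    """Physical shape-function gradients at the 8 Gauss points: (8, 8, 3)."""
    g = 1.0 / np.sqrt(3.0)
    signs = 2.0 * _CORNERS - 1.0  # corner signs in [-1, 1]^3
    pts = g * signs  # Gauss points share the corner pattern
    grads = np.empty((8, 8, 3))
    for q, (xi, eta, zeta) in enumerate(pts):
        for a, (sx, sy, sz) in enumerate(signs):
            grads[q, a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
            grads[q, a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta)
            grads[q, a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta)
    return grads * (2.0 / dx)  # reference -> physical


def element_tensors(grid: TissueGrid, conducting: np.ndarray) -> np.ndarray:
    """(n_cond, 3, 3) conductivity tensors of the conducting elements."""
    f = grid.fiber[conducting]
    sl = grid.sigma_l[conducting]
    st = grid.sigma_t[conducting]
    eye = np.eye(3)
    ff = f[:, :, None] * f[:, None, :]
    return sl[:, None, None] * ff + st[:, None, None] * (eye[None] - ff)


_QCORNERS = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])


def _quad_gauss_gradients(dx: float) -> np.ndarray:
    """Physical shape-function gradients at the 4 Gauss points: (4, 4, 2)."""
    g = 1.0 / np.sqrt(3.0)
    signs = 2.0 * _QCORNERS - 1.0
    pts = g * signs
    grads = np.empty((4, 4, 2))
    for q, (xi, eta) in enumerate(pts):
        for a, (sx, sy) in enumerate(signs):
            grads[q, a, 0] = 0.25 * sx * (1 + sy * eta)
            grads[q, a, 1] = 0.25 * sy * (1 + sx * xi)
    return grads * (2.0 / dx)


def _quad_node_ids(grid: TissueGrid) -> np.ndarray:
    """(n_elements, 4) global node ids (k = 0 plane) for a 1-element sheet."""
    nx, ny, nz = grid.shape
    a, b, c = grid.node_shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    base = np.stack([ii.ravel(), jj.ravel()], axis=1)
    ids = np.empty((base.shape[0], 4), dtype=np.int64)
    for corner, off in enumerate(_QCORNERS):
        node = base + off
        ids[:, corner] = (node[:, 0] * b + node[:, 1]) * c
    return ids


def element_node_ids(grid: TissueGrid) -> np.ndarray:
    """(n_elements, 8) global node ids of every element (C element order)."""
    nx, ny, nz = grid.shape
    a, b, c = grid.node_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)  # (n_elem, 3)
    ids = np.empty((base.shape[0], 8), dtype=np.int64)
    for corner, off in enumerate(_CORNERS):
        node = base + off
        ids[:, corner] = (node[:, 0] * b + node[:, 1]) * c + node[:, 2]
    return ids


class DiffusionOperator:
    """Assembled stiffness/mass system restricted to the conducting domain.

    Attributes
    ----------
    K : csr_matrix
        Stiffness matrix (mS mm) over active nodes; symmetric, zero row
        sums (constants are in its null space).
    mass : ndarray
        Lumped mass per active node, chi_cm * nodal volume (uF).
    active_nodes : ndarray
        Global node ids of the active (conducting-attached) nodes.
    """

    def __init__(self, grid: TissueGrid, chi_cm: float, mass: str = "consistent",
                 theta: float = 1.0):
        if chi_cm <= 0:
            raise ValueError("chi * Cm must be positive")
        if mass not in ("consistent", "lumped", "average"):
            raise ValueError("mass must be 'consistent', 'lumped' or 'average'")
        if not 0.5 <= theta <= 1.0:
            raise ValueError("theta must be in [0.5, 1] (Crank-Nicolson to backward Euler)")
        self.theta = theta
        grid.validate()
        conducting = grid.conducting().ravel()
        if not conducting.any():
            raise ValueError("no conducting elements")
        dx = grid.dx
        self.sheet2d = grid.shape[2] == 1
        tensors = element_tensors(grid, grid.conducting())

        if self.sheet2d:
            # one-element-thick sheet: solve on the k = 0 node plane with
            # 4-node quad elements (thickness dx); requires in-plane fibers
            if np.any(np.abs(grid.fiber[grid.conducting()][:, 2]) > 1e-9):
                raise ValueError("2-D sheet assembly requires in-plane fibers")
            enodes = _quad_node_ids(grid)[conducting]
            B = _quad_gauss_gradients(dx)  # (4, 4, 2)
            detj_w = (dx / 2.0) ** 2 * dx
            ke = np.einsum("qai,nij,qbj->nab", B, tensors[:, :2, :2], B) * detj_w
            ncorner = 4
            vol_corner = dx ** 3 / 4.0
            same = (_QCORNERS[:, None, :] == _QCORNERS[None, :, :]).sum(axis=2)
            me = (dx / 6.0) ** 2 * dx * (2.0 ** same) * chi_cm
        else:
            enodes = element_node_ids(grid)[conducting]
            B = _gauss_gradients(dx)  # (8, 8, 3)
            detj_w = (dx / 2.0) ** 3
            # K_e[a, b] = sum_q B[q, a] . D . B[q, b] * detJ
            ke = np.einsum("qai,nij,qbj->nab", B, tensors, B) * detj_w
            ncorner = 8
            vol_corner = dx ** 3 / 8.0
            same = (_CORNERS[:, None, :] == _CORNERS[None, :, :]).sum(axis=2)
            me = (dx / 6.0) ** 3 * (2.0 ** same) * chi_cm

        self.active_nodes = np.unique(enodes)
        n_act = self.active_nodes.size
        g2a = np.full(grid.n_nodes, -1, dtype=np.int64)
        g2a[self.active_nodes] = np.arange(n_act)
        loc = g2a[enodes]  # (n_cond, ncorner)

        rows = np.repeat(loc, ncorner, axis=1).ravel()
        cols = np.tile(loc, (1, ncorner)).ravel()
        K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_act, n_act))
        self.K = K.tocsr()
        self.K.sum_duplicates()

        vol_node = np.zeros(n_act)
        np.add.at(vol_node, loc.ravel(), vol_corner)
        self.mass = chi_cm * vol_node
        self.mass_kind = mass
        if mass in ("consistent", "average"):
            Mc = sp.coo_matrix((np.tile(me.ravel(), loc.shape[0]), (rows, cols)),
                               shape=(n_act, n_act))
            Mc = Mc.tocsr()
            Mc.sum_duplicates()
            if mass == "average":
                # averaged mass: half consistent, half lumped (minimizes the
                # 1-D dispersion error of the semi-discrete wave operator)
                Mc = 0.5 * (Mc + sp.diags(self.mass).tocsr())
            self.M = Mc
        else:
            self.M = sp.diags(self.mass).tocsr()
        self.enodes_local = loc
        self.global_to_active = g2a
        self.n_active = n_act
        self.chi_cm = chi_cm
        self._factor = None
        self._factor_dt = None
        self._A = None
        self._A_dt = None

    def system_matrix(self, dt: float) -> sp.csr_matrix:
        """Theta-scheme system M + theta dt K (cached per dt)."""
        if self._A is None or self._A_dt != dt:
            self._A = (self.M + self.theta * dt * self.K).tocsr()
            self._A_dt = dt
            self._B = (self.M - (1.0 - self.theta) * dt * self.K).tocsr() \
                if self.theta < 1.0 else None
        return self._A

    def solve_implicit(self, V: np.ndarray, dt: float, method: str = "cg", tol: float = 1e-8):
        """One implicit diffusion step: (M + theta dt K) V_new = (M - (1-theta) dt K) V."""
        A = self.system_matrix(dt)
        rhs = self._B @ V if self._B is not None else self.M @ V
        if method == "lu":
            if self._factor is None or self._factor_dt != dt:
                from scipy.sparse.linalg import splu

                self._factor = splu(A.tocsc())
                self._factor_dt = dt
            return self._factor.solve(rhs)
        from scipy.sparse.linalg import cg

        x, info = cg(A, rhs, x0=V, rtol=tol, maxiter=2000)
        if info != 0:
            raise RuntimeError(f"conjugate gradient failed to converge (info={info})")
        return x


def assemble_diffusion(grid: TissueGrid, chi_cm: float) -> DiffusionOperator:
    """Assemble the diffusion operator for a labeled grid (see class docs)."""
    return DiffusionOperator(grid, chi_cm)
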