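"""Forward ECG pipeline: passive bidomain step and torso Laplace solve.

Extracellular potentials on the heart grid are obtained from the static
passive bidomain relation nabla.((Gi+Ge) grad phi_e) = -nabla.(Gi grad Vm)
under the equal-anisotropy-ratio assumption, with the monodomain
conductivity as the harmonic combination of Gi and Ge.  Body-surface
potentials follow from a Laplace solve over a heterogeneous tetrahedral
torso volume with Dirichlet conditions at the heart-torso interface and
natural (no-flux) Neumann conditions on the torso surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg

from ..solver.diffusion import DiffusionOperator

#: torso regional conductivities (S/m); the unassigned-space value is the
#: average over tissues, the others are literature values
TORSO_CONDUCTIVITIES = {
    "unassigned": 0.239,
    "lungs": 0.0389,
    "liver": 0.147,
    "bone": 0.02,
    "blood": 0.7,
    "myocardium": 0.24,
}


def extracellular_from_vm(op: DiffusionOperator, vm: np.ndarray,
                          extra_to_intra: float = 1.0, tol: float = 1e-10) -> np.ndarray:
    """Extracellular potential phi_e on heart nodes, zero-mean gauge.

    Under equal anisotropy with sigma_e = lambda sigma_i and the
    monodomain tensor as their harmonic mean, the passive bidomain
    equation becomes (1+lambda) K phi_e = -K vm with K the assembled
    monodomain stiffness; phi_e is defined up to a constant, fixed by the
    zero-mean convention.
    """
    lam = extra_to_intra
    if lam <= 0:
        raise ValueError("conductivity ratio must be positive")
    K = op.K
    rhs = -(K @ vm) / (1.0 + lam)
    scale = np.abs(vm).max()
    if np.linalg.norm(rhs) <= 1e-12 * max(scale, 1.0):
        return np.zeros_like(rhs)  # uniform Vm: no gradients, phi_e = 0
    # singular (pure Neumann) but consistent: rhs is orthogonal to constants
    x, info = cg(K, rhs, rtol=tol, atol=0.0, maxiter=5000)
    if info != 0:
        raise RuntimeError(f"extracellular solve did not converge (info={info})")
    return x - x.mean()


@dataclass
class TorsoVolume:
    """A tetrahedral torso mesh with per-element conductivity."""

    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) node indices
    sigma: np.ndarray  # (m,) S/m, isotropic per element
    region: np.ndarray | None = None  # (m,) labels
    heart_nodes: np.ndarray | None = None  # Dirichlet interface node ids
    electrodes: dict = field(default_factory=dict)  # name -> node id

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("conductivities must be positive")


def assemble_tet_stiffness(mesh: TorsoVolume) -> sp.csr_matrix:
    """P1 stiffness matrix sum_e vol_e sigma_e grad_a . grad_b."""
    nd = mesh.nodes
    tets = mesh.tets
    p0 = nd[tets[:, 0]]
    e1 = nd[tets[:, 1]] - p0
    e2 = nd[tets[:, 2]] - p0
    e3 = nd[tets[:, 3]] - p0
    J = np.stack([e1, e2, e3], axis=2)  # (m, 3, 3) columns are edges
    detj = np.linalg.det(J)
    if np.any(np.abs(detj) < 1e-14):
        raise ValueError("degenerate tetrahedra in mesh")
    vol = np.abs(detj) / 6.0
    Jinv = np.linalg.inv(J)
    # gradients of barycentric shape functions: grad lambda_i is row i of J^-1
    g123 = Jinv
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    ke = np.einsum("mai,mbi->mab", grads, grads) * (vol * mesh.sigma)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(nd.shape[0],) * 2)
    return K.tocsr()


def solve_torso(
    mesh: TorsoVolume,
    dirichlet_nodes: np.ndarray,
    dirichlet_values: np.ndarray,
    tol: float = 1e-9,
) -> np.ndarray:
    """Laplace solve: Dirichlet at the given nodes, Neumann elsewhere.

    Jacobi-preconditioned conjugate gradient on the reduced system;
    returns the potential at every mesh node.
    """
    n = mesh.nodes.shape[0]
    K = assemble_tet_stiffness(mesh)
    fixed = np.zeros(n, dtype=bool)
    fixed[np.asarray(dirichlet_nodes, dtype=np.int64)] = True
    phi = np.zeros(n)
    phi[np.asarray(dirichlet_nodes, dtype=np.int64)] = dirichlet_values
    free = ~fixed
    A = K[free][:, free].tocsr()
    b = -K[free][:, fixed] @ phi[fixed]
    # Jacobi-preconditioned CG (symmetric, robust for heterogeneous sigma)
    dinv = 1.0 / A.diagonal()
    M = LinearOperator(A.shape, lambda v: dinv * v)
    x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=20000, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b)
        raise RuntimeError(f"torso solve did not converge (info={info}, residual={res:.2e})")
    phi[free] = x
    return phi


def forward_ecg(
    mesh: TorsoVolume,
    heart_phi_e: np.ndarray,
    times: np.ndarray | None = None,
    tol: float = 1e-9,
):
    """Electrode potentials for a (time x heart-node) phi_e array.

    ``heart_phi_e`` may be 1-D (one instant) or 2-D (n_times x n_heart);
    returns an ECGSet-like dict of per-lead arrays plus the time base.
    """
    if mesh.heart_nodes is None or not mesh.electrodes:
        raise ValueError("mesh needs heart interface nodes and electrodes")
    phi_e = np.atleast_2d(np.asarray(heart_phi_e, dtype=float))
    leads = {name: np.empty(phi_e.shape[0]) for name in mesh.electrodes}
    for it in range(phi_e.shape[0]):
        phi = solve_torso(mesh, mesh.heart_nodes, phi_e[it], tol=tol)
        for name, node in mesh.electrodes.items():
            leads[name][it] = phi[node]
    return {"time": times if times is not None else np.arange(phi_e.shape[0]),
            "leads": leads}


def compare_ecg(simulated: dict, reference: dict, resample: bool = True) -> dict:
    """Per-lead Pearson correlation between two ECG sets.

    ECG sets are ``{"time": array, "leads": {name: array}}``.  With
    ``resample`` the simulated beat is linearly time-rescaled onto the
    reference cycle length before correlating.  Zero-variance leads yield
    NaN.
    """
    out = {}
    common = set(simulated["leads"]) & set(reference["leads"])
    if not common:
        raise ValueError("no common leads")
    t_sim = np.asarray(simulated["time"], dtype=float)
    t_ref = np.asarray(reference["time"], dtype=float)
    for lead in sorted(common):
        s = np.asarray(simulated["leads"][lead], dtype=float)
        r = np.asarray(reference["leads"][lead], dtype=float)
        if resample and s.size > 1 and r.size > 1:
            # map the simulated cycle linearly onto the reference time base
            ts = (t_sim - t_sim[0]) / (t_sim[-1] - t_sim[0])
            tr = (t_ref - t_ref[0]) / (t_ref[-1] - t_ref[0])
            s = np.interp(tr, ts, s)
        n = min(s.size, r.size)
        s, r = s[:n], r[:n]
        if s.std() == 0.0 or r.std() == 0.0:
            out[lead] = float("nan")
            continue
        out[lead] = float(np.corrcoef(s, r)[0, 1])
    return out
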