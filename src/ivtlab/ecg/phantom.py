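"""Synthetic torso and analytic phantoms for the forward-ECG solver.

The box torso is a regular tetrahedralized block with an embedded heart
region and six anterior-surface electrodes (precordial-lead stand-ins).
The spherical-shell wedge carries a closed-form l = 1 Laplace solution
used as an analytic oracle.
"""

from __future__ import annotations

import numpy as np

from .forward import TORSO_CONDUCTIVITIES, TorsoVolume

# Kuhn subdivision of a cube into six tetrahedra sharing the main diagonal
_KUHN = np.array([
    [0, 1, 3, 7],
    [0, 3, 2, 7],
    [0, 2, 6, 7],
    [0, 6, 4, 7],
    [0, 4, 5, 7],
    [0, 5, 1, 7],
])
_CUBE = np.array([
    [0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
    [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1],
])


def _tet_box(shape, spacing):
    nx, ny, nz = shape
    ax, by, cz = nx + 1, ny + 1, nz + 1
    X, Y, Z = np.meshgrid(np.arange(ax), np.arange(by), np.arange(cz), indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) * spacing

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    corner_ids = np.empty((base.shape[0], 8), dtype=np.int64)
    for c, off in enumerate(_CUBE):
        node = base + off
        corner_ids[:, c] = (node[:, 0] * by + node[:, 1]) * cz + node[:, 2]
    tets = corner_ids[:, _KUHN].reshape(-1, 4)
    cell_of_tet = np.repeat(np.arange(base.shape[0]), 6)
    centers = (base + 0.5) * spacing
    return nodes, tets, centers[cell_of_tet]


def box_torso(
    size=(120.0, 80.0, 120.0),
    spacing: float = 10.0,
    heart_center=(60.0, 30.0, 60.0),
    heart_radius: float = 20.0,
    n_electrodes: int = 6,
) -> TorsoVolume:
    """A box torso phantom with a spherical 'heart' region.

    The heart-interface node set is every node inside the heart radius;
    electrodes sit in a row on the anterior face (y = 0) at heart height.
    Regions outside the heart take the unassigned-space conductivity.
    """
    shape = tuple(int(round(s / spacing)) for s in size)
    nodes, tets, tet_centers = _tet_box(shape, spacing)
    heart_center = np.asarray(heart_center, dtype=float)
    d = np.linalg.norm(tet_centers - heart_center, axis=1)
    sigma = np.full(tets.shape[0], TORSO_CONDUCTIVITIES["unassigned"])
    region = np.where(d <= heart_radius, 1, 0)
    sigma[region == 1] = TORSO_CONDUCTIVITIES["myocardium"]

    dn = np.linalg.norm(nodes - heart_center, axis=1)
    heart_nodes = np.nonzero(dn <= heart_radius)[0]

    electrodes = {}
    xs = np.linspace(0.2, 0.8, n_electrodes) * size[0]
    for i, x in enumerate(xs, start=1):
        target = np.array([x, 0.0, heart_center[2]])
        electrodes[f"V{i}"] = int(np.argmin(np.linalg.norm(nodes - target, axis=1)))
    return TorsoVolume(nodes=nodes, tets=tets, sigma=sigma, region=region,
                       heart_nodes=heart_nodes, electrodes=electrodes)


def shell_wedge(
    r_inner: float = 20.0,
    r_outer: float = 60.0,
    theta_deg=(30.0, 150.0),
    n_r: int = 16,
    n_theta: int = 16,
    n_phi: int = 24,
    sigma: float = 0.2,
):
    """Structured tet mesh of a spherical-shell wedge (full revolution).

    Returns ``(TorsoVolume, dirichlet_nodes, exact)`` where ``exact`` is
    the l = 1 Laplace solution phi = (r + b^3/(2 r^2)) cos(theta), which
    satisfies a no-flux condition at the outer radius; Dirichlet data are
    imposed on the inner sphere and on both polar-angle caps.
    """
    th0, th1 = np.deg2rad(theta_deg)
    r = np.linspace(r_inner, r_outer, n_r + 1)
    th = np.linspace(th0, th1, n_theta + 1)
    ph = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)

    def nid(ir, it, ip):
        return (ir * (n_theta + 1) + it) * n_phi + (ip % n_phi)

    R, T, P = np.meshgrid(r, th, ph, indexing="ij")
    nodes = np.stack(
        [
            (R * np.sin(T) * np.cos(P)).ravel(),
            (R * np.sin(T) * np.sin(P)).ravel(),
            (R * np.cos(T)).ravel(),
        ],
        axis=1,
    )

    tets = []
    for ir in range(n_r):
        for it in range(n_theta):
            for ip in range(n_phi):
                corners = [
                    nid(ir, it, ip), nid(ir + 1, it, ip),
                    nid(ir, it + 1, ip), nid(ir + 1, it + 1, ip),
                    nid(ir, it, ip + 1), nid(ir + 1, it, ip + 1),
                    nid(ir, it + 1, ip + 1), nid(ir + 1, it + 1, ip + 1),
                ]
                # map hex corner order (r, theta, phi) -> Kuhn pattern
                hexn = [corners[0], corners[1], corners[2], corners[3],
                        corners[4], corners[5], corners[6], corners[7]]
                for tet in _KUHN:
                    tets.append([hexn[c] for c in tet])
    tets = np.asarray(tets, dtype=np.int64)
    sig = np.full(tets.shape[0], float(sigma))

    rr = np.linalg.norm(nodes, axis=1)
    costh = nodes[:, 2] / np.maximum(rr, 1e-300)
    b = r_outer
    exact = (rr + b ** 3 / (2.0 * rr ** 2)) * costh

    on_inner = np.isclose(rr, r_inner, rtol=1e-9, atol=1e-9)
    theta = np.arccos(np.clip(costh, -1, 1))
    on_caps = np.isclose(theta, th0, atol=1e-9) | np.isclose(theta, th1, atol=1e-9)
    dirichlet = np.nonzero(on_inner | on_caps)[0]

    mesh = TorsoVolume(nodes=nodes, tets=tets, sigma=sig)
    return mesh, dirichlet, exact
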