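"""One-time calibration of the chi * Cm product.

The monodomain equation needs the surface-to-volume ratio chi and the
membrane capacitance per area Cm only through their product.  Neither is
an independently observable tissue-scale quantity here, so the product is
calibrated once so that healthy tissue conducts at 0.68 m/s along the
fiber with sigma_L = 0.24 S/m at 0.4 mm resolution and dt = 0.02 ms, and
is then frozen: every other conduction velocity in the package is a
prediction, not a fit.
"""

from __future__ import annotations

import numpy as np

from ..substrate.fixtures import strand
from .monodomain import ModelVersion, SolverConfig, StimulusDef, TissueModel, run_simulation
from .measures import measure_cv

CV_TARGET = 0.68  # m/s along fiber, healthy tissue
STRAND_LENGTH = 30.0  # mm
STRAND_CROSS = 1.6  # mm


def measure_strand_cv(
    chi_cm: float,
    er: bool = False,
    bz: bool = False,
    bz_set: str = "cv75",
    transverse: bool = False,
    dx: float = 0.4,
    dt: float = 0.02,
    linear_solver: str = "lu",
    mass: str = "consistent",
    theta: float = 1.0,
) -> float:
    """CV on the reference strand for one membrane/conductivity setting.

    The strand runs along x; ``transverse=True`` rotates the fiber field
    to lie across the strand so the measured propagation is cross-fiber.
    ``bz=True`` labels the whole strand border zone (the version's BZ
    conductivity set applies); ``er`` enables ionic remodeling there.
    Measurement sites sit at 1/3 and 2/3 of the strand length.
    """
    fiber = (0.0, 1.0, 0.0) if transverse else (1.0, 0.0, 0.0)
    grid = strand(length=STRAND_LENGTH, cross=STRAND_CROSS, dx=dx, fiber_direction=fiber)
    if bz:
        from ..substrate.volume import LABEL_BZ

        grid.label[:] = LABEL_BZ
    cfg = SolverConfig(dt=dt, chi_cm=chi_cm, linear_solver=linear_solver,
                       mass=mass, theta=theta)
    model = TissueModel(grid, ModelVersion(er=er, bz_set=bz_set), config=cfg)

    # a deep, strong stimulus so that even strongly under-resolved slow media
    # ignite; the measurement sites are far from the stimulated end
    stim_nodes = model.op.active_nodes[model.coords[:, 0] <= 3 * dx + 1e-9]
    stim = StimulusDef(nodes=stim_nodes, onset=0.0, duration=3.0, amplitude=-100.0)
    mid = STRAND_CROSS / 2.0
    a = (STRAND_LENGTH / 3.0, mid, mid)
    b = (2.0 * STRAND_LENGTH / 3.0, mid, mid)
    stop = np.concatenate([model.nodes_near(a, 0.1), model.nodes_near(b, 0.1)])
    # generous ceiling (the slowest media crawl at ~0.03 m/s); the run
    # stops as soon as both sites have activated
    res = run_simulation(model, [stim], duration=1000.0, stop_after_captured=stop)
    return measure_cv(res, model, a, b)


def calibrate_chi_cm(
    target: float = CV_TARGET,
    tol: float = 1e-3,
    max_iter: int = 10,
    dx: float = 0.4,
    dt: float = 0.02,
    mass: str = "consistent",
    theta: float = 1.0,
    verbose: bool = False,
) -> float:
    """Solve for chi*Cm so the healthy along-fiber strand CV hits ``target``.

    Secant iteration on log(chi*Cm) exploiting CV ~ (chi*Cm)^(-1/2);
    converges in a handful of strand simulations.
    """
    x0, x1 = 1.0, 1.4
    f0 = measure_strand_cv(x0, dx=dx, dt=dt, mass=mass, theta=theta) - target
    f1 = measure_strand_cv(x1, dx=dx, dt=dt, mass=mass, theta=theta) - target
    for _ in range(max_iter):
        if abs(f1) < tol:
            return x1
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x2 = min(max(x2, 0.1), 10.0)
        x0, f0 = x1, f1
        x1 = x2
        f1 = measure_strand_cv(x1, dx=dx, dt=dt, mass=mass, theta=theta) - target
        if verbose:
            print(f"chi*Cm = {x1:.5f}, CV = {f1 + target:.4f} m/s")
    if abs(f1) >= tol:
        raise RuntimeError("chi*Cm calibration did not converge")
    return x1
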