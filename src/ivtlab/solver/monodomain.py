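"""Monodomain reaction-diffusion simulation on labeled tissue grids.

Operator splitting per time step (default dt = 0.02 ms): an explicit
adaptive ionic update (Rush-Larsen gates, forward-Euler concentrations)
followed by an implicit backward-Euler diffusion solve (conjugate
gradient, or a cached sparse LU factorization).  Healthy and border-zone
elements carry the ventricular myocyte membrane (border zone optionally
with ionic remodeling), fibrotic elements the fibroblast membrane; scar
elements are excluded from the conducting domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..membrane import fibroblast, tp06
from ..membrane.integrate import DVMAX_DEFAULT, get_tables, step_nodes
from ..membrane.phenotypes import REMODELING_SCALINGS
from ..substrate.grid import TissueGrid
from ..substrate.volume import LABEL_BZ, LABEL_FIBROSIS
from .conductivity import BZ_SETS, ConductivityAssignment
from .diffusion import DiffusionOperator

#: chi * Cm (uF/mm^3) calibrated once so that healthy along-fiber CV is
#: 0.68 m/s at sigma_L = 0.24 S/m on the 0.4 mm reference strand with
#: dt = 0.02 ms (see ``ivtlab.solver.calibrate``); frozen for all
#: experiments thereafter.
CHI_CM_DEFAULT = 2.177079

CTYPE_FIBROBLAST = 3


@dataclass
class SolverConfig:
    """Numerical parameters of the monodomain solver."""

    dt: float = 0.02  # ms
    chi_cm: float = CHI_CM_DEFAULT  # uF/mm^3 (surface-to-volume x capacitance)
    dvmax: float = DVMAX_DEFAULT  # mV per ionic substep
    linear_solver: str = "cg"
    cg_tol: float = 1e-8
    mass: str = "consistent"  # FEM mass treatment: consistent/lumped/average
    theta: float = 1.0  # 1 = backward Euler, 0.5 = Crank-Nicolson
    activation_threshold: float = -20.0  # mV upward crossing = activation event

    def __post_init__(self):
        if self.dt <= 0 or self.chi_cm <= 0:
            raise ValueError("dt and chi*Cm must be positive")


@dataclass
class StimulusDef:
    """A localized transmembrane stimulus train.

    ``nodes`` are global grid node ids; amplitude is a current per unit
    capacitance (pA/pF, negative = depolarizing).
    """

    nodes: np.ndarray
    onset: float
    duration: float = 2.0
    amplitude: float = -52.0
    period: float = 0.0
    count: int = 1

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        if self.count > 1 and self.duration >= self.period:
            raise ValueError("stimulus duration must be shorter than its period")

    def active_at(self, t: float) -> bool:
        rel = t - self.onset
        if rel < 0:
            return False
        if self.count <= 1 or self.period <= 0:
            return rel < self.duration
        k = int(rel // self.period)
        return k < self.count and (rel - k * self.period) < self.duration


@dataclass(frozen=True)
class ModelVersion:
    """A border-zone modeling strategy: ER flag + fibrosis level + BZ set."""

    er: bool = False
    fibrosis_pct: float = 0.0
    bz_set: str = "cv75"

    @property
    def name(self) -> str:
        return f"er_{'on' if self.er else 'off'}_fib{int(round(self.fibrosis_pct))}"


def table1_versions(bz_set: str = "cv75") -> list[ModelVersion]:
    """The eight BZ modeling strategies: ER off/on x 0/10/20/30 % fibrosis."""
    return [
        ModelVersion(er=er, fibrosis_pct=p, bz_set=bz_set)
        for er in (False, True)
        for p in (0.0, 10.0, 20.0, 30.0)
    ]


@dataclass
class TissueState:
    """Membrane state of the active nodes at one instant (checkpointable)."""

    t: float
    V: np.ndarray
    S: np.ndarray

    def copy(self) -> "TissueState":
        return TissueState(t=self.t, V=self.V.copy(), S=self.S.copy())


@dataclass
class SimResult:
    """Output of one monodomain run."""

    times: np.ndarray  # snapshot times (may be empty)
    snapshots: np.ndarray | None  # (n_snap, n_active) Vm
    active_nodes: np.ndarray
    coords: np.ndarray  # (n_active, 3) node coordinates, mm
    first_activation: np.ndarray  # per active node, ms (nan = never)
    activation_count: np.ndarray
    probe_traces: dict
    probe_times: np.ndarray
    ref_activations: dict  # node id -> array of upward-crossing times
    event_log: list
    final_state: TissueState
    config: SolverConfig

    def lat_at(self, node_id: int) -> float:
        idx = np.searchsorted(self.active_nodes, node_id)
        if idx >= self.active_nodes.size or self.active_nodes[idx] != node_id:
            raise KeyError(f"node {node_id} is not in the conducting domain")
        return float(self.first_activation[idx])


class TissueModel:
    """A grid + model version bound to assembled operators and membranes.

    Building the model assigns conductivities for the version's BZ set,
    assembles the diffusion operator and derives per-node membrane
    parameters (majority label over incident conducting elements; ties
    prefer the myocyte membrane).
    """

    def __init__(
        self,
        grid: TissueGrid,
        version: ModelVersion = ModelVersion(),
        config: SolverConfig | None = None,
        conductivities: ConductivityAssignment | None = None,
    ):
        self.grid = grid
        self.version = version
        self.config = config or SolverConfig()
        if conductivities is None:
            conductivities = ConductivityAssignment(bz=BZ_SETS[version.bz_set])
        conductivities.apply(grid)
        self.conductivities = conductivities
        self.op = DiffusionOperator(grid, self.config.chi_cm,
                                    mass=self.config.mass, theta=self.config.theta)
        self._setup_membranes()

    def _setup_membranes(self):
        grid, op = self.grid, self.op
        cond = grid.conducting().ravel()
        labels = grid.label.ravel()[cond]
        layers = grid.layer.ravel()[cond]
        n_act = op.n_active
        loc = op.enodes_local  # (n_cond, 4 or 8)

        lab_counts = np.zeros((n_act, 3), dtype=np.int32)  # healthy, bz, fibrosis
        lay_counts = np.zeros((n_act, 3), dtype=np.int32)
        col = np.zeros_like(labels)
        col[labels == LABEL_BZ] = 1
        col[labels == LABEL_FIBROSIS] = 2
        for corner in range(loc.shape[1]):
            np.add.at(lab_counts, (loc[:, corner], col), 1)
            np.add.at(lay_counts, (loc[:, corner], layers), 1)

        myo = lab_counts[:, 0] + lab_counts[:, 1]
        is_fib = lab_counts[:, 2] > myo  # ties -> myocyte
        is_bz = lab_counts[:, 1] > lab_counts[:, 0]
        layer = np.argmax(lay_counts, axis=1).astype(np.int8)

        ctype = layer.copy()
        ctype[is_fib] = CTYPE_FIBROBLAST
        remodeled = self.version.er & is_bz & ~is_fib

        self.ctype = ctype
        self.sna = np.where(remodeled, REMODELING_SCALINGS["I_Na"], 1.0)
        self.scal = np.where(remodeled, REMODELING_SCALINGS["I_CaL"], 1.0)
        self.skr = np.where(remodeled, REMODELING_SCALINGS["I_Kr"], 1.0)
        self.sks = np.where(remodeled, REMODELING_SCALINGS["I_Ks"], 1.0)
        self.is_fibroblast_node = is_fib
        self.coords = grid.node_coords()[op.active_nodes]

    def resting_state(self, t: float = 0.0) -> TissueState:
        n = self.op.n_active
        V = np.full(n, tp06.V_INIT)
        S = np.zeros((n, tp06.NSTATE))
        S[:] = tp06.STATE_INIT
        fibn = self.is_fibroblast_node
        V[fibn] = fibroblast.V_INIT_FIB
        S[fibn] = 0.0
        S[fibn, 0] = fibroblast.STATE_INIT_FIB[0]
        S[fibn, 1] = fibroblast.STATE_INIT_FIB[1]
        return TissueState(t=t, V=V, S=S)

    def nodes_near(self, point, radius: float = 1.0) -> np.ndarray:
        """Global ids of active nodes within ``radius`` mm of ``point``."""
        d = np.linalg.norm(self.coords - np.asarray(point, dtype=float), axis=1)
        sel = d <= radius
        if not sel.any():
            sel = d <= d.min() + 1e-9  # fall back to the nearest node
        return self.op.active_nodes[sel]

    def local_index(self, node_ids) -> np.ndarray:
        g2a = self.op.global_to_active[np.asarray(node_ids, dtype=np.int64)]
        if np.any(g2a < 0):
            raise KeyError("node outside the conducting domain")
        return g2a


def run_simulation(
    model: TissueModel,
    stimuli: list[StimulusDef],
    duration: float,
    initial: TissueState | None = None,
    probes: dict | None = None,
    reference_nodes=(),
    snapshot_stride: int = 0,
    early_stop_quiescent: bool = False,
    quiescent_threshold: float = -60.0,
    stop_after_captured=(),
    event_log: list | None = None,
) -> SimResult:
    """Advance the tissue model by ``duration`` ms.

    ``probes`` maps names to global node ids whose Vm trace is recorded
    every step; ``reference_nodes`` get all upward threshold-crossing
    times recorded (activation trains, used for reentry detection).  With
    ``early_stop_quiescent`` the run ends once no stimulus is pending and
    every node is below ``quiescent_threshold`` and nearly steady;
    ``stop_after_captured`` (global node ids) ends the run as soon as all
    the listed nodes have activated.  Deterministic for fixed inputs.
    """
    cfg = model.config
    dt = cfg.dt
    op = model.op
    tabs, k1tab = get_tables()
    state = (initial or model.resting_state()).copy()
    V, S = state.V, state.S
    t0 = state.t
    n_act = op.n_active

    stim_loc = [model.local_index(st.nodes) for st in stimuli]
    probes = probes or {}
    probe_loc = {k: model.local_index([v])[0] for k, v in probes.items()}
    probe_hist = {k: [] for k in probes}
    ref_loc = {int(r): model.local_index([r])[0] for r in reference_nodes}
    ref_times = {r: [] for r in ref_loc}

    first_act = np.full(n_act, np.nan)
    act_count = np.zeros(n_act, dtype=np.int32)
    thr = cfg.activation_threshold

    stop_loc = model.local_index(np.asarray(list(stop_after_captured), dtype=np.int64)) \
        if len(stop_after_captured) else None

    log = event_log if event_log is not None else []
    nstep = int(round(duration / dt))
    snap_t, snaps = [], []
    istim = np.zeros(n_act)
    last_stim_end = max((st.onset + (max(st.count, 1) - 1) * st.period + st.duration
                         for st in stimuli), default=t0)

    for step in range(nstep):
        t = t0 + step * dt
        any_stim = False
        for st, locs in zip(stimuli, stim_loc):
            if st.active_at(t):
                if not any_stim:
                    istim[:] = 0.0
                    any_stim = True
                istim[locs] += st.amplitude
        if not any_stim:
            istim[:] = 0.0

        v_old = V.copy()
        step_nodes(V, S, model.ctype, model.sna, model.scal, model.skr,
                   model.sks, istim, dt, cfg.dvmax, tabs, k1tab)
        V_new = op.solve_implicit(V, dt, method=cfg.linear_solver, tol=cfg.cg_tol)
        V[:] = V_new
        t_next = t + dt

        crossed = (v_old < thr) & (V >= thr)
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            newly = idx[np.isnan(first_act[idx])]
            # linear sub-step interpolation of the crossing time
            frac = (thr - v_old[idx]) / (V[idx] - v_old[idx])
            tc = t + frac * dt
            first_act[newly] = t + (thr - v_old[newly]) / (V[newly] - v_old[newly]) * dt
            act_count[idx] += 1
            for r, li in ref_loc.items():
                pos = np.searchsorted(idx, li)
                if pos < idx.size and idx[pos] == li:
                    ref_times[r].append(float(tc[pos]))

        for k, li in probe_loc.items():
            probe_hist[k].append(V[li])
        if snapshot_stride and (step + 1) % snapshot_stride == 0:
            snap_t.append(t_next)
            snaps.append(V.copy())

        if step % 25 == 24 and not np.all(np.isfinite(V)):
            raise FloatingPointError(f"non-finite membrane potential at t = {t_next:.2f} ms")

        if stop_loc is not None and crossed.any() and not np.any(np.isnan(first_act[stop_loc])):
            break

        if (
            early_stop_quiescent
            and t_next > last_stim_end + 20.0
            and step % 50 == 49
            and V.max() < quiescent_threshold
            and np.max(np.abs(V - v_old)) < 0.01 * dt * 50
        ):
            log.append((t_next, "activity extinguished; run stopped early"))
            break

    state.t = t0 + (step + 1) * dt if nstep else t0
    state.V, state.S = V, S
    probe_times = t0 + dt * (1 + np.arange(len(next(iter(probe_hist.values()))) if probe_hist else 0))
    return SimResult(
        times=np.asarray(snap_t),
        snapshots=np.asarray(snaps) if snaps else None,
        active_nodes=op.active_nodes,
        coords=model.coords,
        first_activation=first_act,
        activation_count=act_count,
        probe_traces={k: np.asarray(v) for k, v in probe_hist.items()},
        probe_times=probe_times,
        ref_activations={r: np.asarray(v) for r, v in ref_times.items()},
        event_log=log,
        final_state=state,
        config=cfg,
    )


def stabilize_fibrosis(
    model: TissueModel,
    duration: float = 1000.0,
    extend_if_active: bool = True,
    event_log: list | None = None,
) -> TissueState:
    """Unstimulated run letting myocyte-fibroblast couplings reach steady state.

    Returns the final state, to be used as the initial condition of
    subsequent runs.  Logs whether transient ectopic-like activity
    occurred and checks final quiescence (optionally extending the run
    once if the tissue is still active).
    """
    log = event_log if event_log is not None else []
    res = run_simulation(model, [], duration, event_log=log)
    ectopic = int(np.nansum(res.activation_count))
    if ectopic:
        log.append((duration, f"stabilization transient: {ectopic} activation events"))
    state = res.final_state
    if state.V.max() > -60.0:
        log.append((duration, "tissue not quiescent after stabilization"))
        if extend_if_active:
            res = run_simulation(model, [], duration, initial=state, event_log=log)
            state = res.final_state
            if state.V.max() > -60.0:
                log.append((2 * duration, "warning: still not quiescent after extension"))
    return state
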