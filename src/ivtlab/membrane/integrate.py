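"""Integrators for the membrane models.

Two integration paths are provided:

* the production path: Rush-Larsen updates for the gating variables plus
  forward Euler for potential and concentrations, with per-node adaptive
  substepping (a substep may change the potential by at most
  ``DVMAX_DEFAULT`` mV).  Voltage-dependent rates come from lookup tables
  on a 0.02 mV grid with linear interpolation; the same kernel steps both
  myocyte and fibroblast nodes and is shared by the single-cell drivers
  and the tissue solver.
* a fixed-step 4th-order Runge-Kutta integrator of the exact-formula
  right-hand side, used as an independent oracle at small step sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import fibroblast, tp06
from .phenotypes import MyocytePhenotype

DVMAX_DEFAULT = 0.1  # mV per ionic substep
STIM_AMP_DEFAULT = -52.0  # pA/pF, about twice diastolic threshold
STIM_DUR_DEFAULT = 1.0  # ms

# voltage grid of the rate tables
V_TAB_MIN = -120.0
V_TAB_STEP = 0.02
N_TAB = 10001  # covers [-120, 80] mV

# IK1 rectification table is indexed by V - E_K
U_TAB_MIN = -150.0
U_TAB_STEP = 0.05
N_UTAB = 8001  # covers [-150, 250] mV

# table row indices: 0-10 gate inf, 11-21 gate tau (m h j d f f2 r s_epi
# xr1 xr2 xs), 22/23 endo s gate, 24-29 current factors
ROW_S_INF_ENDO = 22
ROW_S_TAU_ENDO = 23
ROW_T1CAL = 24
ROW_T2CAL = 25
ROW_N1NACA = 26
ROW_N2NACA = 27
ROW_FNAK = 28
ROW_FPK = 29
N_ROWS = 30


def _build_tables():
    vgrid = V_TAB_MIN + V_TAB_STEP * np.arange(N_TAB)
    tabs = np.empty((N_ROWS, N_TAB))
    for i, v in enumerate(vgrid):
        inf_e, tau_e = tp06.gate_rates(v, 2)
        inf_n, tau_n = tp06.gate_rates(v, 0)
        tabs[0:11, i] = inf_e
        tabs[11:22, i] = tau_e
        tabs[ROW_S_INF_ENDO, i] = inf_n[7]
        tabs[ROW_S_TAU_ENDO, i] = tau_n[7]

    rtonf = tp06.RTONF
    vs = vgrid - 15.0
    amp = 4.0 * vs * tp06.FARADAY / rtonf
    expv = np.exp(2.0 * vs / rtonf)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = amp * expv / (expv - 1.0)
        t2 = amp * tp06.CAO / (expv - 1.0)
    sing = np.abs(vs) < 1e-9
    t1[sing] = 2.0 * tp06.FARADAY
    t2[sing] = 2.0 * tp06.FARADAY * tp06.CAO
    tabs[ROW_T1CAL] = t1
    tabs[ROW_T2CAL] = t2

    e1 = np.exp(tp06.GAMMA_NACA * vgrid / rtonf)
    e2 = np.exp((tp06.GAMMA_NACA - 1.0) * vgrid / rtonf)
    denom = (
        (tp06.KMNAI ** 3 + tp06.NAO ** 3)
        * (tp06.KMCA + tp06.CAO)
        * (1.0 + tp06.KSAT * e2)
    )
    tabs[ROW_N1NACA] = tp06.KNACA * e1 * tp06.CAO / denom
    tabs[ROW_N2NACA] = tp06.KNACA * e2 * tp06.NAO ** 3 * tp06.ALPHA_NACA / denom

    tabs[ROW_FNAK] = (
        tp06.PNAK
        * tp06.KO
        / (tp06.KO + tp06.KMK)
        / (1.0 + 0.1245 * np.exp(-0.1 * vgrid / rtonf) + 0.0353 * np.exp(-vgrid / rtonf))
    )
    tabs[ROW_FPK] = tp06.GPK / (1.0 + np.exp((25.0 - vgrid) / 5.98))

    ugrid = U_TAB_MIN + U_TAB_STEP * np.arange(N_UTAB)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (ugrid - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (ugrid + 100.0)) + np.exp(0.1 * (ugrid - 10.0))) / (
        1.0 + np.exp(-0.5 * ugrid)
    )
    k1tab = tp06.GK1 * (ak1 / (ak1 + bk1)) * ugrid
    return tabs, k1tab


_TABLES = None


def get_tables():
    """Rate/current lookup tables, built once per process."""
    global _TABLES
    if _TABLES is None:
        _TABLES = _build_tables()
    return _TABLES


@njit(cache=True, fastmath=True, inline="always")
def _decay(x):
    """exp(-x) with a cheap series fast path for the common small-x case."""
    if x < 0.05:
        return 1.0 - x * (1.0 - 0.5 * x * (1.0 - x / 3.0))
    return np.exp(-x)


@njit(cache=True, fastmath=True, inline="always")
def _interp(row, tabs, v):
    u = (v - V_TAB_MIN) / V_TAB_STEP
    if u < 0.0:
        u = 0.0
    elif u > N_TAB - 1.001:
        u = N_TAB - 1.001
    i = int(u)
    w = u - i
    return tabs[row, i] * (1.0 - w) + tabs[row, i + 1] * w


@njit(cache=True, fastmath=True)
def step_nodes(V, S, ctype, sna, scal, skr, sks, istim, dt, dvmax, tabs, k1tab):
    """Advance every node's membrane by ``dt`` ms (in place).

    ``V`` is (n,), ``S`` is (n, 18); fibroblast nodes (ctype == 3) use the
    first two state columns for their gates.  ``istim`` (pA/pF) is applied
    for the whole interval.  Each node substeps adaptively so that a
    single substep changes its potential by at most ``dvmax`` mV.
    """
    n = V.shape[0]
    rtonf = tp06.RTONF
    for p in range(n):
        ct = ctype[p]
        stim = istim[p]
        if ct == 3:
            # fibroblast node: cheap model, exact rates
            v = V[p]
            remaining = dt
            while remaining > 1e-12:
                dvf = fibroblast.fib_rhs(v, S[p, :2], stim, S[p, 2:4])
                # S[p,2:4] used as scratch for derivatives
                adv = abs(dvf)
                h = remaining
                if adv * h > dvmax:
                    h = dvmax / adv
                r_inf, tau_r, s_inf, tau_s = fibroblast.fib_rates(v)
                v += h * dvf
                S[p, 0] = r_inf + (S[p, 0] - r_inf) * _decay(h / tau_r)
                S[p, 1] = s_inf + (S[p, 1] - s_inf) * _decay(h / tau_s)
                remaining -= h
            V[p] = v
            continue

        gks = sks[p] * tp06.GKS_BY_LAYER[ct]
        gto = tp06.GTO_BY_LAYER[ct]
        gna = sna[p] * tp06.GNA
        gcal = scal[p] * tp06.GCAL
        gkr = skr[p] * tp06.GKR * np.sqrt(tp06.KO / 5.4)

        v = V[p]
        remaining = dt
        while remaining > 1e-12:
            cai = S[p, 13]
            casr = S[p, 14]
            cass = S[p, 15]
            nai = S[p, 16]
            ki = S[p, 17]

            ek = rtonf * np.log(tp06.KO / ki)
            ena = rtonf * np.log(tp06.NAO / nai)
            eks = rtonf * np.log((tp06.KO + tp06.PKNA * tp06.NAO) / (ki + tp06.PKNA * nai))
            eca = 0.5 * rtonf * np.log(tp06.CAO / cai)

            ina = gna * S[p, 0] ** 3 * S[p, 1] * S[p, 2] * (v - ena)
            ical = (
                gcal
                * S[p, 3] * S[p, 4] * S[p, 5] * S[p, 6]
                * (0.25 * cass * _interp(ROW_T1CAL, tabs, v) - _interp(ROW_T2CAL, tabs, v))
            )
            ito = gto * S[p, 7] * S[p, 8] * (v - ek)
            ikr = gkr * S[p, 9] * S[p, 10] * (v - ek)
            iks = gks * S[p, 11] * S[p, 11] * (v - eks)

            uu = (v - ek - U_TAB_MIN) / U_TAB_STEP
            if uu < 0.0:
                uu = 0.0
            elif uu > N_UTAB - 1.001:
                uu = N_UTAB - 1.001
            iu = int(uu)
            wu = uu - iu
            ik1 = k1tab[iu] * (1.0 - wu) + k1tab[iu + 1] * wu

            inaca = _interp(ROW_N1NACA, tabs, v) * nai ** 3 - _interp(ROW_N2NACA, tabs, v) * cai
            inak = _interp(ROW_FNAK, tabs, v) * nai / (nai + tp06.KMNA)
            ipca = tp06.GPCA * cai / (cai + tp06.KPCA)
            ipk = _interp(ROW_FPK, tabs, v) * (v - ek)
            ibna = tp06.GBNA * (v - ena)
            ibca = tp06.GBCA * (v - eca)

            itot = ina + ical + ito + ikr + iks + ik1 + inaca + inak + ipca + ipk + ibna + ibca
            dv = -(itot + stim)

            h = remaining
            adv = abs(dv)
            if adv * h > dvmax:
                h = dvmax / adv

            # calcium machinery and concentration derivatives
            kcasr = tp06.MAXSR - (tp06.MAXSR - tp06.MINSR) / (1.0 + (tp06.EC_SR / casr) ** 2)
            k1r = tp06.K1P / kcasr
            k2r = tp06.K2P * kcasr
            rq = S[p, 12]
            o_rel = k1r * cass * cass * rq / (tp06.K3 + k1r * cass * cass)
            irel = tp06.VREL * o_rel * (casr - cass)
            ileak = tp06.VLEAK * (casr - cai)
            iup = tp06.VMAXUP / (1.0 + (tp06.KUP / cai) ** 2)
            ixfer = tp06.VXFER * (cass - cai)

            bc = 1.0 / (1.0 + tp06.BUFC * tp06.KBUFC / ((cai + tp06.KBUFC) ** 2))
            bsr = 1.0 / (1.0 + tp06.BUFSR * tp06.KBUFSR / ((casr + tp06.KBUFSR) ** 2))
            bss = 1.0 / (1.0 + tp06.BUFSS * tp06.KBUFSS / ((cass + tp06.KBUFSS) ** 2))

            dcai = bc * (
                -(ibca + ipca - 2.0 * inaca) * tp06.CAPACITANCE / (2.0 * tp06.VC * tp06.FARADAY)
                - (iup - ileak) * tp06.VSR / tp06.VC
                + ixfer
            )
            dcasr = bsr * (iup - irel - ileak)
            dcass = bss * (
                -ical * tp06.CAPACITANCE / (2.0 * tp06.VSS * tp06.FARADAY)
                + irel * tp06.VSR / tp06.VSS
                - ixfer * tp06.VC / tp06.VSS
            )
            dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * tp06.CAPACITANCE / (
                tp06.VC * tp06.FARADAY
            )
            dki = -(ik1 + ito + ikr + iks + ipk - 2.0 * inak + stim) * tp06.CAPACITANCE / (
                tp06.VC * tp06.FARADAY
            )

            # Rush-Larsen gate updates
            for g in range(11):
                row = g
                trow = 11 + g
                if g == 7 and ct == 0:  # endo s gate
                    row = ROW_S_INF_ENDO
                    trow = ROW_S_TAU_ENDO
                ginf = _interp(row, tabs, v)
                gtau = _interp(trow, tabs, v)
                # table order m h j d f f2 r s xr1 xr2 xs maps to state
                # columns 0 1 2 3 4 5 7 8 9 10 11 (6 is fcass)
                col = g if g < 6 else g + 1
                S[p, col] = ginf + (S[p, col] - ginf) * _decay(h / gtau)

            fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
            tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
            S[p, 6] = fcass_inf + (S[p, 6] - fcass_inf) * _decay(h / tau_fcass)

            a_rq = tp06.K4
            b_rq = k2r * cass
            rq_inf = a_rq / (a_rq + b_rq)
            tau_rq = 1.0 / (a_rq + b_rq)
            S[p, 12] = rq_inf + (rq - rq_inf) * _decay(h / tau_rq)

            S[p, 13] = cai + h * dcai
            S[p, 14] = casr + h * dcasr
            S[p, 15] = cass + h * dcass
            S[p, 16] = nai + h * dnai
            S[p, 17] = ki + h * dki

            v += h * dv
            remaining -= h
        V[p] = v
    return


@njit(cache=True)
def _rk4_run(V0, S0, ctype, sna, scal, skr, sks, duration, dt, stim_onsets, stim_dur, stim_amp, stride):
    nstep = int(round(duration / dt))
    nsamp = nstep // stride + 1
    tout = np.empty(nsamp)
    vout = np.empty(nsamp)
    S = S0.copy()
    v = V0
    k1 = np.empty(tp06.NSTATE)
    k2 = np.empty(tp06.NSTATE)
    k3 = np.empty(tp06.NSTATE)
    k4 = np.empty(tp06.NSTATE)
    tmp = np.empty(tp06.NSTATE)
    tout[0] = 0.0
    vout[0] = v
    isamp = 1
    for step in range(nstep):
        t = step * dt
        stim = 0.0
        for so in stim_onsets:
            if so <= t < so + stim_dur:
                stim = stim_amp
        dv1 = tp06.tt06_rhs(v, S, ctype, sna, scal, skr, sks, stim, k1)
        for i in range(tp06.NSTATE):
            tmp[i] = S[i] + 0.5 * dt * k1[i]
        dv2 = tp06.tt06_rhs(v + 0.5 * dt * dv1, tmp, ctype, sna, scal, skr, sks, stim, k2)
        for i in range(tp06.NSTATE):
            tmp[i] = S[i] + 0.5 * dt * k2[i]
        dv3 = tp06.tt06_rhs(v + 0.5 * dt * dv2, tmp, ctype, sna, scal, skr, sks, stim, k3)
        for i in range(tp06.NSTATE):
            tmp[i] = S[i] + dt * k3[i]
        dv4 = tp06.tt06_rhs(v + dt * dv3, tmp, ctype, sna, scal, skr, sks, stim, k4)
        v += dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
        for i in range(tp06.NSTATE):
            S[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % stride == 0:
            tout[isamp] = t + dt
            vout[isamp] = v
            isamp += 1
    return tout[:isamp], vout[:isamp], v, S


def integrate_rk4(
    phenotype: MyocytePhenotype,
    duration: float,
    dt: float = 0.001,
    V0: float | None = None,
    S0: np.ndarray | None = None,
    stim_onsets=(),
    stim_dur: float = STIM_DUR_DEFAULT,
    stim_amp: float = STIM_AMP_DEFAULT,
    sample_dt: float = 0.02,
):
    """Fixed-step 4th-order Runge-Kutta oracle on the exact-formula RHS."""
    if V0 is None:
        V0 = tp06.V_INIT
    if S0 is None:
        S0 = tp06.STATE_INIT.copy()
    sna, scal, skr, sks = phenotype.scaling_tuple()
    stride = max(1, int(round(sample_dt / dt)))
    t, v, vf, sf = _rk4_run(
        V0, np.asarray(S0, dtype=float), phenotype.ctype, sna, scal, skr, sks,
        duration, dt, np.asarray(stim_onsets, dtype=float), stim_dur, stim_amp, stride,
    )
    return t, v, vf, sf


@njit(cache=True)
def _rl_run(V0, S0, ctype, sna, scal, skr, sks, duration, dt, dvmax,
            stim_onsets, stim_dur, stim_amp, tabs, k1tab):
    nstep = int(round(duration / dt))
    tout = np.empty(nstep + 1)
    vout = np.empty(nstep + 1)
    V = np.empty(1)
    V[0] = V0
    S = S0.reshape(1, -1).copy()
    ct = np.empty(1, dtype=np.int8)
    ct[0] = ctype
    a_sna = np.full(1, sna)
    a_scal = np.full(1, scal)
    a_skr = np.full(1, skr)
    a_sks = np.full(1, sks)
    ist = np.zeros(1)
    tout[0] = 0.0
    vout[0] = V0
    for step in range(nstep):
        t = step * dt
        stim = 0.0
        for so in stim_onsets:
            if so <= t < so + stim_dur:
                stim = stim_amp
        ist[0] = stim
        step_nodes(V, S, ct, a_sna, a_scal, a_skr, a_sks, ist, dt, dvmax, tabs, k1tab)
        tout[step + 1] = t + dt
        vout[step + 1] = V[0]
    return tout, vout, V[0], S[0]


@dataclass
class Trace:
    """A single-cell membrane-potential trace."""

    t: np.ndarray
    v: np.ndarray
    captured: bool = True
    final_state: np.ndarray | None = field(default=None, repr=False)
    final_v: float | None = None

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"time_ms": self.t, "Vm_mV": self.v}).to_csv(path, index=False)


def pace_single_cell(
    phenotype: MyocytePhenotype,
    bcl: float,
    n_beats: int,
    stim_amp: float = STIM_AMP_DEFAULT,
    stim_dur: float = STIM_DUR_DEFAULT,
    dt: float = 0.02,
    dvmax: float = DVMAX_DEFAULT,
    V0: float | None = None,
    S0: np.ndarray | None = None,
) -> Trace:
    """Pace a single myocyte and return the trace of the final beat.

    Integration is Rush-Larsen/forward-Euler with adaptive substepping
    (the production path).  A beat with no crossing of 0 mV is flagged as
    not captured.
    """
    if bcl <= 0:
        raise ValueError("BCL must be positive")
    if n_beats < 1:
        raise ValueError("need at least one beat")
    tabs, k1tab = get_tables()
    if V0 is None:
        V0 = tp06.V_INIT
    if S0 is None:
        S0 = tp06.STATE_INIT.copy()
    sna, scal, skr, sks = phenotype.scaling_tuple()
    onsets = np.arange(n_beats) * bcl
    t, v, vf, sf = _rl_run(
        V0, np.asarray(S0, dtype=float), phenotype.ctype, sna, scal, skr, sks,
        n_beats * bcl, dt, dvmax, onsets, stim_dur, stim_amp, tabs, k1tab,
    )
    last = t >= (n_beats - 1) * bcl
    tl = t[last] - (n_beats - 1) * bcl
    vl = v[last]
    captured = bool(np.max(vl) > 0.0)
    return Trace(t=tl, v=vl, captured=captured, final_state=sf, final_v=vf)


@njit(cache=True)
def _pair_run(Vm0, Sm0, ctype, sna, scal, skr, sks, Vf0, Sf0, g_gap_npf,
              n_fibs, cap_ratio, duration, dt, dvmax, stim_onsets, stim_dur,
              stim_amp, tabs, k1tab):
    # myocyte + n fibroblasts coupled by a gap conductance (nS normalised
    # by myocyte capacitance -> g_gap_npf in nS/pF_myocyte)
    nstep = int(round(duration / dt))
    tout = np.empty(nstep + 1)
    vout = np.empty(nstep + 1)
    vfout = np.empty(nstep + 1)
    V = np.empty(2)
    V[0] = Vm0
    V[1] = Vf0
    S = np.zeros((2, tp06.NSTATE))
    S[0] = Sm0
    S[1, 0] = Sf0[0]
    S[1, 1] = Sf0[1]
    ct = np.empty(2, dtype=np.int8)
    ct[0] = ctype
    ct[1] = 3
    a_sna = np.full(2, sna)
    a_scal = np.full(2, scal)
    a_skr = np.full(2, skr)
    a_sks = np.full(2, sks)
    ist = np.zeros(2)
    tout[0] = 0.0
    vout[0] = Vm0
    vfout[0] = Vf0
    for step in range(nstep):
        t = step * dt
        stim = 0.0
        for so in stim_onsets:
            if so <= t < so + stim_dur:
                stim = stim_amp
        # coupling current, frozen over the step (outward positive)
        icoup_m = n_fibs * g_gap_npf * (V[0] - V[1])
        icoup_f = g_gap_npf * cap_ratio * (V[1] - V[0])
        ist[0] = stim + icoup_m
        ist[1] = icoup_f
        step_nodes(V, S, ct, a_sna, a_scal, a_skr, a_sks, ist, dt, dvmax, tabs, k1tab)
        tout[step + 1] = t + dt
        vout[step + 1] = V[0]
        vfout[step + 1] = V[1]
    return tout, vout, vfout, V, S


def pace_coupled_pair(
    phenotype: MyocytePhenotype,
    g_gap_ns: float,
    bcl: float,
    n_beats: int,
    n_fibroblasts: int = 2,
    stim_amp: float = STIM_AMP_DEFAULT,
    stim_dur: float = STIM_DUR_DEFAULT,
    dt: float = 0.02,
):
    """Pace a myocyte electrotonically coupled to fibroblasts.

    ``g_gap_ns`` is the gap-junctional conductance per fibroblast in nS
    (published estimates span roughly 0.3-8 nS).  Returns the final-beat
    myocyte trace and the fibroblast potential trace.
    """
    tabs, k1tab = get_tables()
    cm_myo = 185.0  # pF
    cm_fib = 6.3  # pF
    g_npf = g_gap_ns / cm_myo
    cap_ratio = cm_myo / cm_fib
    sna, scal, skr, sks = phenotype.scaling_tuple()
    onsets = np.arange(n_beats) * bcl
    t, vm, vf, Vfin, Sfin = _pair_run(
        tp06.V_INIT, tp06.STATE_INIT.copy(), phenotype.ctype, sna, scal, skr, sks,
        fibroblast.V_INIT_FIB, fibroblast.STATE_INIT_FIB.copy(), g_npf,
        n_fibroblasts, cap_ratio, n_beats * bcl, dt, DVMAX_DEFAULT,
        onsets, stim_dur, stim_amp, tabs, k1tab,
    )
    last = t >= (n_beats - 1) * bcl
    tl = t[last] - (n_beats - 1) * bcl
    myo = Trace(t=tl, v=vm[last], captured=bool(np.max(vm[last]) > 0.0))
    fib = Trace(t=tl, v=vf[last])
    return myo, fib


def myocyte_rhs(V, S, phenotype: MyocytePhenotype, istim: float = 0.0):
    """Time derivatives (dV, dS) of the myocyte model at one state point."""
    V = float(V)
    S = np.asarray(S, dtype=float)
    if not np.isfinite(V) or not np.all(np.isfinite(S)):
        raise ValueError("non-finite state")
    dS = np.empty(tp06.NSTATE)
    sna, scal, skr, sks = phenotype.scaling_tuple()
    dV = tp06.tt06_rhs(V, S, phenotype.ctype, sna, scal, skr, sks, istim, dS)
    return dV, dS


def fibroblast_rhs(Vf, Sf, i_coupling: float = 0.0):
    """Time derivatives (dVf, dSf) of the fibroblast model."""
    Vf = float(Vf)
    Sf = np.asarray(Sf, dtype=float)
    if not np.isfinite(Vf) or not np.all(np.isfinite(Sf)):
        raise ValueError("non-finite state")
    dS = np.empty(fibroblast.NSTATE_FIB)
    dV = fibroblast.fib_rhs(Vf, Sf, i_coupling, dS)
    return dV, dS
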