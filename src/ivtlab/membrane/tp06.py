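"""Human ventricular myocyte model (ten Tusscher & Panfilov 2006 formulation).

State layout (18 variables besides the membrane potential ``V`` in mV)::

    0  m      INa activation
    1  h      INa fast inactivation
    2  j      INa slow inactivation
    3  d      ICaL activation
    4  f      ICaL voltage inactivation (slow)
    5  f2     ICaL voltage inactivation (fast)
    6  fcass  ICaL subspace-Ca inactivation
    7  r      Ito activation
    8  s      Ito inactivation (layer-dependent kinetics)
    9  xr1    IKr activation
    10 xr2    IKr inactivation
    11 xs     IKs activation
    12 Rq     ryanodine-receptor adaptation variable (R-bar)
    13 Cai    cytosolic Ca (mM)
    14 CaSR   sarcoplasmic-reticulum Ca (mM)
    15 CaSS   dyadic-subspace Ca (mM)
    16 Nai    intracellular Na (mM)
    17 Ki     intracellular K (mM)

Transmural phenotype codes: 0 endo, 1 M, 2 epi (code 3 is reserved for the
fibroblast membrane in tissue-level state arrays).  Currents are expressed
per unit membrane capacitance (pA/pF), so dV/dt = -(sum I_ion + I_stim).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 18

# physical constants
R_GAS = 8314.472  # mJ/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY  # mV

# external concentrations (mM)
KO = 5.4
CAO = 2.0
NAO = 140.0

# cell geometry / capacitance (volumes in um^3 scaled as in the published code)
VC = 0.016404
VSR = 0.001094
VSS = 0.00005468
CAPACITANCE = 0.185

# maximal conductances (nS/pF) and transport parameters
GNA = 14.838
GK1 = 5.405
GKR = 0.153
PKNA = 0.03
GCAL = 0.0000398
GBNA = 0.00029
GBCA = 0.000592
KMK = 1.0
KMNA = 40.0
PNAK = 2.724
KNACA = 1000.0
KMNAI = 87.5
KMCA = 1.38
KSAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5
GPCA = 0.1238
KPCA = 0.0005
GPK = 0.0146

# layer-dependent conductances: endo, M, epi
GKS_BY_LAYER = (0.392, 0.098, 0.392)
GTO_BY_LAYER = (0.073, 0.294, 0.294)

# calcium handling
VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC_SR = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

#: published resting initial condition (V then the 18 states above)
V_INIT = -86.2
STATE_INIT = np.array(
    [
        0.0,      # m
        0.75,     # h
        0.75,     # j
        0.0,      # d
        1.0,      # f
        1.0,      # f2
        1.0,      # fcass
        0.0,      # r
        1.0,      # s
        0.0,      # xr1
        1.0,      # xr2
        0.0,      # xs
        1.0,      # Rq
        0.00007,  # Cai
        1.3,      # CaSR
        0.00007,  # CaSS
        7.67,     # Nai
        138.3,    # Ki
    ]
)

STATE_NAMES = (
    "m", "h", "j", "d", "f", "f2", "fcass", "r", "s", "xr1", "xr2", "xs",
    "Rq", "Cai", "CaSR", "CaSS", "Nai", "Ki",
)


@njit(cache=True, fastmath=True)
def gate_rates(V, ctype):
    """Voltage-dependent gate steady states and time constants.

    Returns two length-12 arrays (inf, tau) for the gates m h j d f f2 r s
    xr1 xr2 xs plus a trailing unused slot kept for alignment; ``fcass``
    and ``Rq`` depend on subspace calcium and are handled separately.
    Order: m h j d f f2 r s xr1 xr2 xs (11 used entries).
    """
    inf = np.empty(11)
    tau = np.empty(11)

    # INa gates
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau[0] = am * bm

    inf[1] = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 310000.0 * np.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)

    inf[2] = inf[1]
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = (
            (-25428.0 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # ICaL voltage gates
    inf[3] = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd

    inf[4] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau[4] = (
        1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0))
        + 20.0
    )

    inf[5] = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau[5] = (
        562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))
    )

    # Ito gates
    inf[6] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau[6] = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    if ctype == 0:  # endocardial s gate
        inf[7] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau[7] = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        inf[7] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau[7] = (
            85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0))
            + 3.0
        )

    # IKr gates
    inf[8] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    ax1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bx1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau[8] = ax1 * bx1

    inf[9] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    ax2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bx2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[9] = ax2 * bx2

    # IKs gate
    inf[10] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau[10] = axs * bxs + 80.0

    return inf, tau


@njit(cache=True, fastmath=True)
def tt06_rhs(V, S, ctype, s_na, s_cal, s_kr, s_ks, istim, dS):
    """Exact-formula time derivatives of the ventricular myocyte model.

    Parameters are the membrane potential ``V`` (mV), state vector ``S``
    (length 18, see module docstring), the transmural phenotype code,
    multiplicative scalings of g_Na/g_CaL/g_Kr/g_Ks (border-zone
    remodeling uses 0.38/0.31/0.30/0.20), and the stimulus current
    (pA/pF, negative = depolarizing).  Fills ``dS`` and returns dV/dt.
    """
    m, h, j = S[0], S[1], S[2]
    d, f, f2, fcass = S[3], S[4], S[5], S[6]
    r, s = S[7], S[8]
    xr1, xr2, xs = S[9], S[10], S[11]
    rq = S[12]
    cai, casr, cass = S[13], S[14], S[15]
    nai, ki = S[16], S[17]

    ek = RTONF * np.log(KO / ki)
    ena = RTONF * np.log(NAO / nai)
    eks = RTONF * np.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * np.log(CAO / cai)

    gks = s_ks * GKS_BY_LAYER[ctype]
    gto = GTO_BY_LAYER[ctype]

    ina = s_na * GNA * m * m * m * h * j * (V - ena)

    vshift = V - 15.0
    expv = np.exp(2.0 * vshift / RTONF)
    if abs(vshift) < 1e-6:
        # limit of the GHK-type driving term at V = 15 mV
        ical_drive = 2.0 * FARADAY * (0.25 * cass - CAO) + vshift * 0.0
    else:
        amp = 4.0 * vshift * FARADAY / RTONF
        ical_drive = amp * (0.25 * cass * expv - CAO) / (expv - 1.0)
    ical = s_cal * GCAL * d * f * f2 * fcass * ical_drive

    ito = gto * r * s * (V - ek)
    ikr = s_kr * GKR * np.sqrt(KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = gks * xs * xs * (V - eks)

    u = V - ek
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
        1.0 + np.exp(-0.5 * u)
    )
    ik1 = GK1 * (ak1 / (ak1 + bk1)) * u

    inaca = (
        KNACA
        * (
            np.exp(GAMMA_NACA * V / RTONF) * nai ** 3 * CAO
            - np.exp((GAMMA_NACA - 1.0) * V / RTONF) * NAO ** 3 * cai * ALPHA_NACA
        )
        / (
            (KMNAI ** 3 + NAO ** 3)
            * (KMCA + CAO)
            * (1.0 + KSAT * np.exp((GAMMA_NACA - 1.0) * V / RTONF))
        )
    )

    inak = (
        PNAK
        * KO
        / (KO + KMK)
        * nai
        / (nai + KMNA)
        / (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF) + 0.0353 * np.exp(-V / RTONF))
    )

    ipca = GPCA * cai / (cai + KPCA)
    ipk = GPK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = GBNA * (V - ena)
    ibca = GBCA * (V - eca)

    itot = ina + ical + ito + ikr + iks + ik1 + inaca + inak + ipca + ipk + ibna + ibca

    # gates
    inf, tau = gate_rates(V, ctype)
    dS[0] = (inf[0] - m) / tau[0]
    dS[1] = (inf[1] - h) / tau[1]
    dS[2] = (inf[2] - j) / tau[2]
    dS[3] = (inf[3] - d) / tau[3]
    dS[4] = (inf[4] - f) / tau[4]
    dS[5] = (inf[5] - f2) / tau[5]
    dS[7] = (inf[6] - r) / tau[6]
    dS[8] = (inf[7] - s) / tau[7]
    dS[9] = (inf[8] - xr1) / tau[8]
    dS[10] = (inf[9] - xr2) / tau[9]
    dS[11] = (inf[10] - xs) / tau[10]

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    dS[6] = (fcass_inf - fcass) / tau_fcass

    # calcium release machinery
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    dS[12] = -k2 * cass * rq + K4 * (1.0 - rq)
    o_rel = k1 * cass * cass * rq / (K3 + k1 * cass * cass)
    irel = VREL * o_rel * (casr - cass)

    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    bc = 1.0 / (1.0 + BUFC * KBUFC / ((cai + KBUFC) ** 2))
    bsr = 1.0 / (1.0 + BUFSR * KBUFSR / ((casr + KBUFSR) ** 2))
    bss = 1.0 / (1.0 + BUFSS * KBUFSS / ((cass + KBUFSS) ** 2))

    dS[13] = bc * (
        -(ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * VC * FARADAY)
        - (iup - ileak) * VSR / VC
        + ixfer
    )
    dS[14] = bsr * (iup - irel - ileak)
    dS[15] = bss * (
        -ical * CAPACITANCE / (2.0 * VSS * FARADAY)
        + irel * VSR / VSS
        - ixfer * VC / VSS
    )
    dS[16] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (VC * FARADAY)
    dS[17] = -(ik1 + ito + ikr + iks + ipk - 2.0 * inak + istim) * CAPACITANCE / (
        VC * FARADAY
    )

    return -(itot + istim)
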