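"""Active human ventricular fibroblast membrane (MacCannell et al. 2007).

The fibroblast carries a time- and voltage-dependent K+ current (I_Kv,
gates ``r`` and ``s``), an inward-rectifying K+ current, a Na+/K+ pump and
a background Na+ current.  Intracellular concentrations are held fixed
(the fibroblast has no appreciable Ca handling), so the state is
``(Vf, r, s)``.  Currents are per unit capacitance (pA/pF); resting
potential is near -49.6 mV, which makes coupled fibroblasts current
sources against a resting myocyte and sinks during its plateau.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE_FIB = 2

KO_F = 5.3581
NAO_F = 130.011
KI_F = 129.4349
NAI_F = 8.5547

RTONF_F = 8314.472 * 306.15 / 96485.3415  # MacCannell experiments at 33 C

G_KV = 0.25      # nS/pF
G_K1 = 0.4822    # nS/pF
G_BNA = 0.0095   # nS/pF
INAK_MAX = 2.002  # pA/pF
KM_K = 1.0
KM_NA = 11.0
V_REV = -150.0
B_NAK = -200.0

V_INIT_FIB = -49.6
STATE_INIT_FIB = np.array([0.0, 1.0])  # r, s


@njit(cache=True, fastmath=True)
def fib_rates(V):
    """Steady states and time constants of the I_Kv gates (r, s)."""
    r_inf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * np.exp(-(((V + 20.0) / 25.9) ** 2))
    s_inf = 1.0 / (1.0 + np.exp((V + 23.0) / 7.0))
    tau_s = 1574.0 + 5268.0 * np.exp(-(((V + 23.0) / 22.7) ** 2))
    return r_inf, tau_r, s_inf, tau_s


@njit(cache=True, fastmath=True)
def fib_rhs(V, S, i_coupling, dS):
    """Time derivatives of the fibroblast model.

    ``i_coupling`` is an extra current (pA/pF, positive = outward) through
    gap-junctional coupling or a tissue stimulus.  Fills ``dS`` (length 2)
    and returns dVf/dt.
    """
    r, s = S[0], S[1]
    ek = RTONF_F * np.log(KO_F / KI_F)
    ena = RTONF_F * np.log(NAO_F / NAI_F)

    i_kv = G_KV * r * s * (V - ek)
    i_k1 = G_K1 * (V - ek) / (1.0 + np.exp(0.0896 * (V - ek)))
    i_nak = (
        INAK_MAX
        * (KO_F / (KO_F + KM_K))
        * (NAI_F ** 1.5 / (NAI_F ** 1.5 + KM_NA ** 1.5))
        * (V - V_REV)
        / (V - B_NAK)
    )
    i_bna = G_BNA * (V - ena)

    r_inf, tau_r, s_inf, tau_s = fib_rates(V)
    dS[0] = (r_inf - r) / tau_r
    dS[1] = (s_inf - s) / tau_s

    return -(i_kv + i_k1 + i_nak + i_bna + i_coupling)
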