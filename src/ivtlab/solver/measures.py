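"""Activation/repolarization measurement: CV, LAT and APD maps."""

from __future__ import annotations

import numpy as np

from .monodomain import SimResult, TissueModel


class ConductionBlockError(RuntimeError):
    """Raised when a measurement site was never captured ("block")."""


def site_lat(result: SimResult, model: TissueModel, point) -> float:
    """First-activation time (ms) of the active node nearest ``point``."""
    d = np.linalg.norm(result.coords - np.asarray(point, dtype=float), axis=1)
    lat = float(result.first_activation[np.argmin(d)])
    if np.isnan(lat):
        raise ConductionBlockError(f"site {tuple(point)} was not captured (block)")
    return lat


def measure_cv(result: SimResult, model: TissueModel, site_a, site_b) -> float:
    """Conduction velocity between two captured sites, in m/s.

    CV = distance / (LAT_b - LAT_a); sites should be aligned with the
    propagation axis, away from the stimulus and the boundaries.  mm/ms
    equals m/s numerically.
    """
    la = site_lat(result, model, site_a)
    lb = site_lat(result, model, site_b)
    if lb == la:
        raise ConductionBlockError("equal activation times; sites too close")
    dist = float(np.linalg.norm(np.asarray(site_b, dtype=float) - np.asarray(site_a, dtype=float)))
    return dist / abs(lb - la)


def compute_lat_apd_maps(result: SimResult, window: tuple[float, float],
                         min_upstroke: float = 5.0, repol_frac: float = 0.9):
    """Per-node LAT and APD90 maps from stored Vm snapshots.

    LAT is the time of maximum dVm/dt within the window; APD is the time
    from LAT until Vm first falls below peak - ``repol_frac`` x (peak -
    baseline), with the baseline taken at the window start.  Nodes whose
    maximum upstroke velocity stays below ``min_upstroke`` mV/ms are
    marked not activated (NaN), as are nodes that do not repolarize
    within the window.
    """
    if result.snapshots is None:
        raise ValueError("run_simulation needs snapshot_stride > 0 to build maps")
    t0, t1 = window
    sel = (result.times >= t0) & (result.times <= t1)
    if sel.sum() < 3:
        raise ValueError("window contains fewer than 3 snapshots")
    t = result.times[sel]
    v = result.snapshots[sel]  # (nt, n)

    dvdt = np.diff(v, axis=0) / np.diff(t)[:, None]
    i_up = np.argmax(dvdt, axis=0)
    n = v.shape[1]
    cols = np.arange(n)
    up_slope = dvdt[i_up, cols]
    lat = t[i_up]
    activated = up_slope >= min_upstroke

    baseline = v[0]
    apd = np.full(n, np.nan)
    for j in cols[activated]:
        seg = v[i_up[j]:, j]
        ts = t[i_up[j]:]
        k_peak = int(np.argmax(seg))
        vpeak = seg[k_peak]
        v90 = vpeak - repol_frac * (vpeak - baseline[j])
        below = np.nonzero(seg[k_peak:] <= v90)[0]
        if below.size:
            apd[j] = ts[k_peak + below[0]] - lat[j]
    lat = np.where(activated, lat, np.nan)
    return lat, apd
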