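"""Action-potential biomarkers from a membrane-potential trace.

APD90 is measured from the time of maximum upstroke velocity to 90 %
repolarization toward the per-beat minimum; AP amplitude is the peak
potential minus the takeoff (pre-upstroke) potential.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

UPSTROKE_THRESHOLD = 5.0  # mV/ms; below this a trace is considered quiescent


@dataclass
class BiomarkerSet:
    """Key AP biomarkers; fields are ``None`` for a quiescent trace."""

    apd90: float | None
    apa: float | None
    rmp: float
    dvdt_max: float | None
    v_peak: float | None

    def to_dict(self):
        return asdict(self)


def compute_biomarkers(t: np.ndarray, v: np.ndarray) -> BiomarkerSet:
    """Biomarkers of the first action potential in ``(t, v)``.

    A trace whose maximum upstroke velocity stays below
    ``UPSTROKE_THRESHOLD`` mV/ms is treated as quiescent: only the
    resting potential (minimum of the trace) is reported.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or t.size < 3:
        raise ValueError("need matching 1-D time/potential arrays with >= 3 samples")

    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[i_up])
    rmp = float(np.min(v))

    if dvdt_max < UPSTROKE_THRESHOLD:
        return BiomarkerSet(apd90=None, apa=None, rmp=rmp, dvdt_max=None, v_peak=None)

    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_peak = float(v[i_peak])
    takeoff = float(np.min(v[: i_up + 1])) if i_up > 0 else float(v[0])
    apa = v_peak - takeoff

    v_min = float(np.min(v[i_peak:]))
    v90 = v_peak - 0.9 * (v_peak - v_min)
    below = np.nonzero(v[i_peak:] <= v90)[0]
    if below.size == 0:
        apd90 = None
    else:
        k = i_peak + below[0]
        # linear interpolation of the crossing time
        if k > 0 and v[k - 1] > v90 and v[k] != v[k - 1]:
            frac = (v[k - 1] - v90) / (v[k - 1] - v[k])
            t90 = t[k - 1] + frac * (t[k] - t[k - 1])
        else:
            t90 = t[k]
        apd90 = float(t90 - t[i_up])
    return BiomarkerSet(apd90=apd90, apa=apa, rmp=rmp, dvdt_max=dvdt_max, v_peak=v_peak)
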