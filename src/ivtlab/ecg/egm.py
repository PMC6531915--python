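"""Electrogram processing: LAT annotation and mapping-point filtering.

Annotation follows the clinical convention for contact mapping: the local
activation time is the deflection of the distal bipolar electrogram
closest to the point of maximum negative slope of the distal unipolar
signal.  Points with a peak-to-peak bipolar amplitude under 0.5 mV are
non-excitable (dense scar) and discarded before any temporal filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMPLITUDE_FLOOR_MV = 0.5
DEFLECTION_NOISE_FRAC = 0.05  # of the bipolar peak-to-peak amplitude


@dataclass
class EGMTrace:
    """A distal unipolar electrode pair and its derived bipolar signal."""

    t: np.ndarray  # ms
    unipolar1: np.ndarray  # mV
    unipolar2: np.ndarray  # mV

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.unipolar1 = np.asarray(self.unipolar1, dtype=float)
        self.unipolar2 = np.asarray(self.unipolar2, dtype=float)
        if not (self.t.shape == self.unipolar1.shape == self.unipolar2.shape):
            raise ValueError("time and unipolar channels must have equal length")

    @property
    def bipolar(self) -> np.ndarray:
        return self.unipolar1 - self.unipolar2

    @property
    def bipolar_p2p(self) -> float:
        b = self.bipolar
        return float(b.max() - b.min())


@dataclass(eq=False)
class MappingPoint:
    """A catheter mapping point: position, electrograms and annotation."""

    position: np.ndarray
    trace: EGMTrace
    lat: float | None = None
    amplitude: float = field(init=False)
    valid: bool = True
    reason: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.amplitude = self.trace.bipolar_p2p


def annotate_lat(trace: EGMTrace) -> float | None:
    """LAT of one electrogram, or None for a flat/featureless trace.

    t* is the time of the steepest negative unipolar slope; the LAT is
    the bipolar deflection (local extremum of |bipolar| above 5 % of its
    peak-to-peak amplitude) nearest to t*.
    """
    u = trace.unipolar1
    if np.ptp(u) == 0.0:
        return None
    du = np.gradient(u, trace.t)
    t_star = trace.t[int(np.argmin(du))]

    b = np.abs(trace.bipolar)
    floor = DEFLECTION_NOISE_FRAC * trace.bipolar_p2p
    if floor == 0.0:
        return None
    # local maxima of |bipolar| above the noise floor
    interior = (b[1:-1] >= b[:-2]) & (b[1:-1] >= b[2:]) & (b[1:-1] > floor)
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return None
    times = trace.t[idx]
    return float(times[np.argmin(np.abs(times - t_star))])


def annotate_point(point: MappingPoint) -> MappingPoint:
    """Amplitude screening plus LAT annotation for one mapping point."""
    if point.amplitude < AMPLITUDE_FLOOR_MV:
        point.valid = False
        point.reason = "low_voltage"
        point.lat = None
        return point
    lat = annotate_lat(point.trace)
    if lat is None:
        point.valid = False
        point.reason = "no_annotation"
    else:
        point.lat = lat
    return point


def filter_points(
    points: list[MappingPoint],
    neighbor_radius: float = 10.0,
    coherence_threshold: float | None = None,
) -> list[MappingPoint]:
    """Amplitude filter, then spatio-temporal LAT coherence filter.

    The amplitude filter (< 0.5 mV -> non-excitable) strictly precedes the
    coherence filter.  A point is incoherent when its LAT deviates from
    the inverse-distance-weighted mean LAT of its neighbors (within
    ``neighbor_radius`` mm) by more than the threshold (default: 3x the
    median absolute residual of the current surviving set).  Incoherent
    points are peeled one at a time — worst first, residuals recomputed
    after each removal — so that a single outlier does not contaminate
    its neighbors' residuals, and re-running the filter on its own
    output removes nothing (the peeling loop terminates at a fixed
    point).  Rejection reasons are recorded; the filtered list is
    returned.
    """
    for p in points:
        if p.valid and p.amplitude < AMPLITUDE_FLOOR_MV:
            p.valid = False
            p.reason = "low_voltage"
            p.lat = None
        elif p.valid and p.lat is None:
            annotate_point(p)

    survivors = [p for p in points if p.valid and p.lat is not None]
    while len(survivors) >= 3:
        pos = np.array([p.position for p in survivors])
        lats = np.array([p.lat for p in survivors])
        resid = np.full(len(survivors), np.nan)
        for i in range(len(survivors)):
            d = np.linalg.norm(pos - pos[i], axis=1)
            nb = (d > 0) & (d <= neighbor_radius)
            if not nb.any():
                continue
            w = 1.0 / d[nb]
            resid[i] = abs(lats[i] - np.sum(w * lats[nb]) / np.sum(w))
        finite = resid[np.isfinite(resid)]
        thr = coherence_threshold
        if thr is None:
            thr = 3.0 * float(np.median(finite)) if finite.size else np.inf
        worst = int(np.nanargmax(resid)) if np.isfinite(resid).any() else -1
        if worst < 0 or not (resid[worst] > thr):
            break
        bad = survivors.pop(worst)
        bad.valid = False
        bad.reason = "incoherent_lat"
    return survivors
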