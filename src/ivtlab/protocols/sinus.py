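"""LAT-driven multi-site sinus stimulation schedules.

The schedule reproduces a mapped activation sequence: each mapping point
becomes a stimulation site fired at its local activation time relative to
the earliest point, repeated every basic cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..solver.monodomain import StimulusDef, TissueModel


@dataclass
class SinusSchedule:
    """Sites with firing offsets (ms), a BCL and a beat count."""

    sites: list  # of (point, offset) pairs; points are mm coordinates
    bcl: float
    n_beats: int

    def stimulus_defs(self, model: TissueModel, radius: float = 1.0,
                      duration: float = 2.0, amplitude: float = -52.0) -> list[StimulusDef]:
        """Concrete stimulus trains on a tissue model (1 mm site radius)."""
        return [
            StimulusDef(
                nodes=model.nodes_near(point, radius),
                onset=offset,
                duration=duration,
                amplitude=amplitude,
                period=self.bcl,
                count=self.n_beats,
            )
            for point, offset in self.sites
        ]


def build_sinus_schedule(points, bcl: float, n_beats: int) -> SinusSchedule:
    """Schedule from (site, LAT) pairs: offsets = LAT - min(LAT).

    Beat k fires each site at its offset + k * BCL; the earliest-activated
    site fires at t = 0.  Duplicate sites with conflicting LATs are an
    error.
    """
    if not points:
        raise ValueError("need at least one (site, LAT) point")
    seen = {}
    for site, lat in points:
        key = tuple(np.round(np.asarray(site, dtype=float), 9))
        if key in seen and abs(seen[key] - lat) > 1e-9:
            raise ValueError(f"site {key} appears twice with conflicting LATs")
        seen[key] = float(lat)
    lat0 = min(seen.values())
    sites = [(np.array(k), v - lat0) for k, v in seen.items()]
    sites.sort(key=lambda sv: sv[1])
    return SinusSchedule(sites=sites, bcl=bcl, n_beats=n_beats)
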