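"""Tissue conductivity assignment by label.

Values are in S/m (numerically equal to mS/mm, the internal unit system
mm/ms/mV).  The three border-zone sets correspond to longitudinal
conduction-velocity reductions of about 75, 50 and 25 % relative to
healthy tissue when combined with the remodeled membrane; the same BZ
conductivities are used whether or not ionic remodeling is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..substrate.grid import TissueGrid
from ..substrate.volume import LABEL_BZ, LABEL_FIBROSIS, LABEL_HEALTHY, LABEL_SCAR

#: named border-zone (sigma_L, sigma_T) sets, keyed by the approximate CV
#: reduction they produce with the remodeled membrane
BZ_SETS = {
    "cv75": (0.05, 0.01),
    "cv50": (0.12, 0.03),
    "cv25": (0.22, 0.0485),
}


@dataclass(frozen=True)
class ConductivityAssignment:
    healthy: tuple[float, float] = (0.24, 0.0456)
    bz: tuple[float, float] = BZ_SETS["cv75"]
    fibrosis: float = 0.1  # isotropic

    def __post_init__(self):
        vals = (*self.healthy, *self.bz, self.fibrosis)
        if any(v <= 0 for v in vals):
            raise ValueError("conductivities must be positive")
        if self.healthy[0] < self.healthy[1] or self.bz[0] < self.bz[1]:
            raise ValueError("sigma_L must be >= sigma_T")

    @classmethod
    def with_bz_set(cls, name: str) -> "ConductivityAssignment":
        return cls(bz=BZ_SETS[name])

    def apply(self, grid: TissueGrid) -> TissueGrid:
        """Fill the grid's per-element sigma_l / sigma_t from its labels."""
        import numpy as np

        sl = np.zeros(grid.shape)
        st = np.zeros(grid.shape)
        lab = grid.label
        sl[lab == LABEL_HEALTHY], st[lab == LABEL_HEALTHY] = self.healthy
        sl[lab == LABEL_BZ], st[lab == LABEL_BZ] = self.bz
        sl[lab == LABEL_FIBROSIS] = self.fibrosis
        st[lab == LABEL_FIBROSIS] = self.fibrosis
        # scar carries no conductivity: excluded from the conducting domain
        sl[lab == LABEL_SCAR] = 0.0
        st[lab == LABEL_SCAR] = 0.0
        grid.sigma_l = sl
        grid.sigma_t = st
        return grid
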