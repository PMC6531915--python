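"""Transmural myocyte phenotypes and border-zone ionic remodeling."""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from . import tp06

LAYERS = ("endo", "M", "epi")
LAYER_CODES = {"endo": 0, "M": 1, "epi": 2}

#: conductance down-scalings measured in epicardial border-zone myocytes
#: (I_Na to 38%, I_CaL to 31%, I_Kr to 30%, I_Ks to 20% of normal)
REMODELING_SCALINGS: Mapping[str, float] = MappingProxyType(
    {"I_Na": 0.38, "I_CaL": 0.31, "I_Kr": 0.30, "I_Ks": 0.20}
)

_NO_SCALING: Mapping[str, float] = MappingProxyType(
    {"I_Na": 1.0, "I_CaL": 1.0, "I_Kr": 1.0, "I_Ks": 1.0}
)


@dataclass(frozen=True)
class MyocytePhenotype:
    """A transmural layer plus optional border-zone remodeling.

    ``conductance_scalings`` multiply the published base maximal
    conductances; scalings are always applied to the base values so the
    derivation is idempotent.
    """

    layer: str
    remodeled: bool
    conductance_scalings: Mapping[str, float] = field(default_factory=lambda: _NO_SCALING)

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown transmural layer {self.layer!r}; expected one of {LAYERS}")
        if any(v <= 0 for v in self.conductance_scalings.values()):
            raise ValueError("conductance scalings must be strictly positive")

    @property
    def ctype(self) -> int:
        """Integer layer code used by the compiled kernels (0 endo, 1 M, 2 epi)."""
        return LAYER_CODES[self.layer]

    @property
    def g_na(self) -> float:
        return self.conductance_scalings["I_Na"] * tp06.GNA

    @property
    def g_cal(self) -> float:
        return self.conductance_scalings["I_CaL"] * tp06.GCAL

    @property
    def g_kr(self) -> float:
        return self.conductance_scalings["I_Kr"] * tp06.GKR

    @property
    def g_ks(self) -> float:
        return self.conductance_scalings["I_Ks"] * tp06.GKS_BY_LAYER[self.ctype]

    @property
    def g_to(self) -> float:
        return tp06.GTO_BY_LAYER[self.ctype]

    def scaling_tuple(self):
        """(s_Na, s_CaL, s_Kr, s_Ks) for the compiled kernels."""
        c = self.conductance_scalings
        return (c["I_Na"], c["I_CaL"], c["I_Kr"], c["I_Ks"])


def derive_phenotype(layer: str, remodeled: bool = False) -> MyocytePhenotype:
    """Return the phenotype for a transmural layer, optionally remodeled.

    Remodeling applies the border-zone scalings multiplicatively to the
    *base* maximal conductances (pure and idempotent).
    """
    scalings = REMODELING_SCALINGS if remodeled else _NO_SCALING
    return MyocytePhenotype(layer=layer, remodeled=remodeled, conductance_scalings=scalings)
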