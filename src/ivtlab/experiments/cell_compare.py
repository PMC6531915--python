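"""Single-cell comparisons: border-zone remodeling and fibroblast coupling."""

from __future__ import annotations

import json
from pathlib import Path

from ..membrane import (
    compute_biomarkers,
    derive_phenotype,
    pace_coupled_pair,
    pace_single_cell,
)


def run_cell_compare(
    out_dir: str | Path | None = None,
    layer: str = "epi",
    bcl: float = 800.0,
    n_beats: int = 10,
    g_gap_ns: float = 3.0,
    n_fibroblasts: int = 2,
) -> dict:
    """Healthy vs remodeled AP biomarkers, and coupled vs uncoupled myocyte.

    Remodeling direction expected: APD90 prolonged, upstroke velocity and
    amplitude reduced.  Fibroblast coupling direction expected: resting
    potential elevated (less negative), APD90 shortened.
    """
    healthy = derive_phenotype(layer, remodeled=False)
    remodeled = derive_phenotype(layer, remodeled=True)

    tr_h = pace_single_cell(healthy, bcl, n_beats)
    tr_r = pace_single_cell(remodeled, bcl, n_beats)
    bm_h = compute_biomarkers(tr_h.t, tr_h.v)
    bm_r = compute_biomarkers(tr_r.t, tr_r.v)

    tr_c, _ = pace_coupled_pair(healthy, g_gap_ns, bcl, n_beats,
                                n_fibroblasts=n_fibroblasts)
    bm_c = compute_biomarkers(tr_c.t, tr_c.v)

    report = {
        "layer": layer,
        "bcl_ms": bcl,
        "healthy": bm_h.to_dict(),
        "remodeled": bm_r.to_dict(),
        "coupled_to_fibroblasts": bm_c.to_dict(),
        "g_gap_ns": g_gap_ns,
        "n_fibroblasts": n_fibroblasts,
        "directions": {
            "remodeled_apd90_prolonged": bm_r.apd90 > bm_h.apd90,
            "remodeled_dvdtmax_reduced": bm_r.dvdt_max < bm_h.dvdt_max,
            "remodeled_apa_reduced": bm_r.apa < bm_h.apa,
            "coupled_rmp_elevated": bm_c.rmp > bm_h.rmp,
            "coupled_apd90_shortened": bm_c.apd90 < bm_h.apd90,
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tr_h.to_csv(out_dir / "trace_healthy.csv")
        tr_r.to_csv(out_dir / "trace_remodeled.csv")
        tr_c.to_csv(out_dir / "trace_coupled.csv")
        (out_dir / "cell_compare.json").write_text(json.dumps(report, indent=2))
    return report
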