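"""Qualitative forward-ECG pipeline check on a phantom torso.

A paced miniature tissue slab provides transmembrane potentials; the
passive bidomain step yields extracellular potentials, which drive a
Laplace solve through the box torso phantom to six anterior electrodes.
This is a smoke test of the whole chain (patient-scale ECG comparison is
out of reach of a desk-scale fixture), so the checks are qualitative:
non-flat leads, gauge invariance and polarity flip under source reversal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..ecg.forward import compare_ecg, extracellular_from_vm, forward_ecg
from ..ecg.phantom import box_torso
from ..solver.monodomain import (
    CHI_CM_DEFAULT,
    ModelVersion,
    SolverConfig,
    StimulusDef,
    TissueModel,
    run_simulation,
)
from ..substrate.fixtures import slab


def run_ecg_smoke(out_dir: str | Path | None = None, snapshot_ms: float = 10.0,
                  beat_ms: float = 320.0) -> dict:
    """One paced slab beat propagated to the phantom torso electrodes."""
    grid = slab(8.0, 8.0, 2.0, dx=0.4)
    cfg = SolverConfig(chi_cm=CHI_CM_DEFAULT, linear_solver="lu")
    model = TissueModel(grid, ModelVersion(), config=cfg)
    stim = StimulusDef(
        nodes=model.op.active_nodes[model.coords[:, 0] <= 0.8 + 1e-9],
        onset=0.0, duration=2.0, amplitude=-80.0,
    )
    stride = int(round(snapshot_ms / cfg.dt))
    res = run_simulation(model, [stim], beat_ms, snapshot_stride=stride)

    phi_e = np.stack([
        extracellular_from_vm(model.op, vm) for vm in res.snapshots
    ])

    torso = box_torso()
    heart_center = np.array([60.0, 30.0, 60.0])
    heart_pos = torso.nodes[torso.heart_nodes]
    # nearest-node transfer of phi_e from the tissue slab (rescaled to the
    # torso heart region) onto the heart-interface nodes
    src = model.coords - model.coords.mean(axis=0)
    span = max(np.ptp(src, axis=0).max(), 1e-9)
    src_scaled = src * (30.0 / span) + heart_center
    nearest = np.array([
        np.argmin(np.linalg.norm(src_scaled - hp, axis=1)) for hp in heart_pos
    ])
    heart_phi = phi_e[:, nearest]

    ecg = forward_ecg(torso, heart_phi, times=res.times, tol=1e-8)
    flipped = forward_ecg(torso, -heart_phi, times=res.times, tol=1e-8)

    amplitudes = {k: float(np.ptp(v)) for k, v in ecg["leads"].items()}
    self_corr = compare_ecg(ecg, ecg, resample=False)
    polarity_flip = all(
        np.allclose(flipped["leads"][k], -ecg["leads"][k], atol=1e-6)
        for k in ecg["leads"]
    )
    report = {
        "lead_peak_to_peak_mV": amplitudes,
        "all_leads_nonflat": bool(all(a > 0 for a in amplitudes.values())),
        "self_correlation": self_corr,
        "polarity_flips_with_source": bool(polarity_flip),
        "n_snapshots": int(len(res.times)),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        df = pd.DataFrame({"time_ms": ecg["time"], **ecg["leads"]})
        df.to_csv(out_dir / "ecg_leads.csv", index=False)
        (out_dir / "ecg_smoke.json").write_text(json.dumps(report, indent=2))
    return report
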