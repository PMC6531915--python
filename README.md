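# ivtlab

**In-silico ventricular-tachycardia laboratory**: simulation of infarct
border-zone electrophysiology — from a delayed-enhancement-MRI-like
intensity volume to programmed-stimulation reentry experiments and
forward ECGs.

Chronic myocardial infarction leaves a non-conducting scar surrounded by
a *border zone* (BZ) of surviving but remodeled myocardium, often with a
*slow conducting channel* (isthmus) of viable tissue crossing the scar.
Such channels sustain reentrant ventricular tachycardia (VT) and are the
targets of catheter ablation.  `ivtlab` implements the computational
pipeline used to study how BZ modeling choices affect VT inducibility:

* **Membrane models** — the ten Tusscher–Panfilov (2006) human
  ventricular action potential with endo/M/epi phenotypes; BZ
  *electrical remodeling* (ER) as conductance down-scaling
  (g_Na → 0.38, g_CaL → 0.31, g_Kr → 0.30, g_Ks → 0.20 of normal); the
  MacCannell (2007) active fibroblast for fibrotic tissue.
* **Substrate synthesis** — synthetic DE-MRI volumes (remote Normal
  intensities, hyper-enhanced scar, BZ rim, through-scar channel,
  correlated noise); SD-method segmentation (scar ≥ mean+3·SD of remote,
  BZ in [mean+2·SD, mean+3·SD)); voxel-to-element mapping;
  intensity-ranked patchy fibrosis at 0/10/20/30 % of the BZ; rule-based
  fibers and 17/41/42 % transmural layers; strand/slab/isthmus fixtures.
* **Monodomain solver** — anisotropic reaction–diffusion
  χC_m ∂V/∂t = ∇·(σ∇V) − χ I_ion with σ = σ_L f fᵀ + σ_T (I − f fᵀ),
  trilinear hexahedral FEM, operator splitting (implicit diffusion at
  dt = 0.02 ms, adaptive Rush–Larsen ionic update), scar as an internal
  no-flux boundary; LAT/APD/CV measurement.
* **Protocols** — LAT-driven multi-site sinus schedules; the clinical
  S1–S2(–S3) programmed-stimulation protocol (6 × 600 ms drive, S2 from
  400 ms decrementing 10 ms, S3 at the same coupling interval); reentry
  detection and the 8-version × pacing-site inducibility table.
* **Forward ECG** — passive-bidomain extracellular potentials
  ((1+λ)Kφ_e = −KV_m under equal anisotropy), torso Laplace solve
  (P1 tetrahedra, CG), electrode extraction, waveform correlation.

## Worked example

Pace a border-zone-remodeled epicardial cell to steady state and report
its biomarkers:

```bash
$ ivtlab cell-simulate --layer epi --remodeled --bcl 800 --beats 10 --out trace.csv
{
  "apd90": 351.70161222485734,
  "apa": 106.37486130434753,
  "rmp": -86.02363133458235,
  "dvdt_max": 210.40965256337836,
  "v_peak": 20.35122996976519
}
```

The remodeled cell's APD90 (352 ms) is prolonged relative to the healthy
epicardial cell (304 ms with the same pacing), while its upstroke
velocity (210 vs 397 mV/ms) and amplitude (106 vs 127 mV) are reduced —
the hallmark of the reduced I_Na/I_CaL and repolarization reserve in the
border zone.  `trace.csv` holds the final-beat membrane potential.

Other entry points (each writes JSON/CSV artifacts under `--out`):

```bash
ivtlab cv-suite                  # calibrate chi*Cm, measure the CV table
ivtlab cell-compare              # healthy vs remodeled vs fibroblast-coupled
ivtlab inducibility --seed 1     # PES VT test on the isthmus fixture (long)
ivtlab ecg-smoke                 # forward-ECG pipeline on the phantom torso
ivtlab substrate-synth --seed 7 --out vol.nii.gz
ivtlab report --run-dir results  # aggregate artifacts
```

On the shipped isthmus fixture, the version with electrical remodeling
is inducible at the first coupling interval — unidirectional block at
the narrow lower channel mouth followed by sustained reentry (cycle
length ≈ 600 ms, 100 bpm) — while the version without remodeling
conducts through the channel at every coupling interval and never
reenters.  See `docs/methods.md` for the models, numerical scheme,
fixture design and limitations.

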