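# Methods

`ivtlab` simulates the electrophysiology of chronically infarcted
ventricular tissue — scar, border zone (BZ) and patchy fibrosis — and the
programmed-stimulation experiments used to probe ventricular-tachycardia
(VT) inducibility, together with a forward-ECG pipeline through a torso
volume conductor.  This note records the models, the numerical choices,
what the synthetic data emulate, and the known limitations.

## Membrane models

Working myocardium uses the ten Tusscher–Panfilov (2006) human
ventricular action-potential model with the published endocardial, M-cell
and epicardial parameter sets (selected per element by transmural layer).
Border-zone *electrical remodeling* (ER) multiplies four maximal
conductances by factors measured in epicardial border-zone myocytes:
I_Na × 0.38, I_CaL × 0.31, I_Kr × 0.30, I_Ks × 0.20.  These scalings are
always applied to the published base values, so deriving a phenotype is
idempotent.  The resulting single-cell phenotype at a cycle length of
800 ms shows a prolonged APD90 and a reduced upstroke velocity and
amplitude relative to the healthy cell — the directions the remodeling
literature reports — and these directions are asserted by the test suite
rather than stated here as numbers.

Fibrotic tissue carries the MacCannell (2007) *active fibroblast*
membrane (I_Kv with two gates, inward-rectifier, Na/K pump, background
Na; fixed intracellular concentrations; resting potential near −49.6 mV).
Fibroblasts therefore act as current sources against resting myocytes
(raising their resting potential) and as sinks during the plateau
(shortening APD).  For the zero-dimensional direction test a myocyte is
coupled to `n` fibroblasts through an explicit gap conductance
(default 3 nS per fibroblast, configurable over the published 0.3–8 nS
range); in tissue, myocyte–fibroblast interaction is mediated entirely by
the diffusion operator, matching the tissue-conductivity approach of the
organ-scale model.

### Integration

The production integrator is Rush–Larsen for all gating variables and
forward Euler for the potential and concentrations, with per-node
adaptive substepping: a substep may move the membrane potential by at
most 0.1 mV (an accuracy choice validated against the oracle below; at a
0.2 mV cap the upstroke error slightly exceeds 1 mV).  Voltage-dependent
rates are tabulated on a 0.02 mV grid with linear interpolation; the
small-`x` exponential in the Rush–Larsen update uses a cubic series fast
path (error < 1e−6 for x < 0.05).  The independent oracle is a fixed-step
classical Runge–Kutta integration of the exact closed-form right-hand
side at dt = 0.001 ms; the production path agrees with it pointwise
within 1 mV over a full action potential for all six phenotypes, which
simultaneously bounds the table-interpolation error.

Biomarkers: APD90 is measured from the time of maximum upstroke velocity
to 90 % repolarization toward the per-beat minimum; AP amplitude is peak
minus takeoff potential.  The model does not define its own biomarker
conventions, so these are package conventions, stated here once.

## Substrate synthesis

The synthetic delayed-enhancement volume emulates the image features the
segmentation pipeline needs, not radiological realism: a Normal remote
intensity distribution (mean μ_r, SD s_r), an ellipsoidal hyper-enhanced
scar plateau (≥ 3 s_r above μ_r; default 5 s_r), a border-zone rim whose
noise-free intensity decays linearly from just under μ_r + 3 s_r at the
scar edge to μ_r + 2 s_r at the outer rim, a lower-intensity channel of
surviving tissue crossing the scar, and spatially correlated Gaussian
noise (Gaussian-filtered white noise, renormalized to zero mean and unit
SD, scaled by s_r).  Correlated noise is what makes the brightest BZ
voxels cluster, so that intensity-ranked fibrosis selection produces
patches rather than salt-and-pepper; the tests verify that the mean
fibrotic-patch size grows with the correlation length.

SD-method classification inside the infarct region of interest: scar iff
I ≥ mean + 3 SD of remote myocardium, BZ iff mean + 2 SD ≤ I < mean + 3 SD,
healthy below.  Closed-left intervals make the boundary deterministic.
Remote statistics are computed per slice by default (each slice
containing infarct ROI must contain remote ROI; the error names the
offending slice), with a global mode available.  If the remote SD is
exactly zero (degenerate synthetic input) only strictly hyper-enhanced
voxels are called scar, so a uniform volume classifies as healthy.

Voxel-to-element transfer assigns each hexahedral element the value of
the voxel containing its centroid; at 1.4 mm voxels and 0.4 mm elements
one voxel feeds up to 64 elements.  Fibrosis at level p% relabels exactly
round(p/100 × N_BZ) border-zone elements in descending mapped intensity,
ties broken by ascending element index (stable sort), deterministically.

Rule-based fibers: the helix angle varies linearly with normalized
transmural depth between configurable endocardial/epicardial limits
(default +60°/−60°), the transverse angle tilts the fiber out of the
tangent plane (default 0°), and optional 3-D Gaussian smoothing is
followed by renormalization.  Transmural layers split the wall at
normalized depths 0.17 and 0.58 (endo/M/epi = 17/41/42 % of thickness).

## Monodomain solver

Tissue is a regular hexahedral grid with per-element conductivity tensor
σ_L f fᵀ + σ_T (I − f fᵀ).  Conductivities (S/m): healthy (0.24, 0.0456);
border zone (0.05, 0.01) in every model version regardless of the ER
flag, with two milder alternatives (0.12, 0.03) and (0.22, 0.0485);
fibrosis isotropic 0.1.  Scar elements are removed from the conducting
domain, which realizes the internal no-flux boundary at the scar
interface; the outer boundary is no-flux naturally.

Spatial discretization is trilinear hexahedral Galerkin FEM with full
2×2×2 Gauss quadrature and a **consistent (non-lumped) mass matrix**;
one-element-thick sheets are assembled as 4-node quad elements on a
single node plane (the two planes of the equivalent hex problem are
identical by symmetry).  Time integration is Godunov operator splitting
per dt = 0.02 ms: the adaptive ionic update described above, then an
implicit backward-Euler diffusion solve, by conjugate gradient
(tolerance 1e−8) or a cached sparse LU factorization — both solve the
same system; CG is the default, LU is used by the long-running
experiment drivers.  A θ-scheme (down to Crank–Nicolson) and a
lumped/averaged mass option exist for numerical experiments.

The consistent-mass choice is deliberate and was selected *before*
freezing the calibration, by comparing lumped, averaged and consistent
mass (and θ = 0.5/1.0) on the wave-propagation benchmarks: at 0.4 mm the
depolarization wavefront (≲ 0.3 mm wide transverse to the fibers) is
under-resolved, and mass lumping slows under-resolved propagation
severely (transverse conduction 10–20 % slower than the consistent-mass
result, with outright conduction failure in the slowest border-zone
settings).  Consistent mass is the standard Galerkin formulation and was
the most accurate of the standard options against near-converged
fine-grid solutions.  Under-resolution is also why the slow transverse
border-zone velocities remain scheme-sensitive; see "Limitations".

χ·Cm (surface-to-volume ratio × membrane capacitance) enters only as a
product.  It is calibrated **once**, by secant iteration, so that healthy
along-fiber conduction on the 0.4 mm reference strand at σ_L = 0.24 S/m
and dt = 0.02 ms is 0.68 m/s, and then frozen (2.177 µF/mm³); every other
conduction velocity in the package is a prediction of that single
calibration, not a fit.

Node membranes on mixed grids follow a majority rule over the incident
conducting elements (ties prefer the myocyte membrane); ER applies to
nodes whose incident elements are majority border zone.  Activation
events are recorded as upward crossings of −20 mV with sub-step linear
interpolation; LAT/APD *maps* are computed post hoc from stored snapshots
with LAT = time of maximum dV/dt in the analysis window and APD measured
to 90 % repolarization toward the window-start baseline.  Conduction
velocity is distance over activation-time difference between two sites
aligned with propagation, away from stimulus and boundaries; the CV rigs
use a 30 × 1.6 × 1.6 mm strand (the 20 × 20 × 6 mm slab gives the same
planar-wave result at higher cost) with a deep 3-element, −100 pA/pF,
3 ms end stimulus so that even strongly under-resolved slow media ignite.

Myocyte–fibroblast stabilization: models containing fibrosis first run
1 s without stimulus; the final state (logged for transient ectopic-like
activity and checked for quiescence, with one optional extension) is the
initial condition of subsequent runs.

## Programmed stimulation and reentry

The PES protocol is six S1 stimuli at a 600 ms cycle length, then a
premature S2 coupled at 400 ms, decrementing in 10 ms steps until VT is
induced or the pacing site fails to capture (local potential does not
cross 0 mV within 10 ms of the stimulus); on capture failure without VT
the scan restarts with an added S3 coupled at the same interval as S2
(joint decrement from the initial interval).  The S1 drive is simulated
once per model and checkpointed; every coupling interval restarts from
that state.  Sustained reentry is declared when a reference node distal
to the pacing site activates at least 3 times after the last stimulus
has ended (3 unsupported cycles distinguishes reentry from a single
echo beat; the protocol does not prescribe a count), and the VT cycle
length is the mean inter-activation interval there.

Attempts advance in 150 ms chunks and close early on one of three
verdicts, which keeps the scan affordable without changing outcomes:
capture failure at the site; sustained reentry; or *antegrade transit* —
on channel fixtures, once the premature wave has crossed the channel
bottom-up (lower, middle, upper landmarks in order) it has annihilated
against the outer wave and no reentrant pathway remains for that
coupling interval.  Attempts that extinguish (quiescent tissue) also
close early.  Block classification uses the channel-interior landmarks:
if the channel midpoint first activates from the upper end, entry from
below failed while entry from above succeeded — unidirectional block at
the lower mouth; a channel that never activates is a bidirectional
block.  A shallow penetration of the lowest ~1 mm of the channel does
not count as entry.

### The isthmus fixture

The shipped reentry substrate is a one-element-thick sheet
(39.6 × 48 mm, dx = 0.6 mm, ~3500 nodes) with two scar blocks separated
by a vertical border-zone channel that tapers from a 2.4 mm lower mouth
to a 6 mm upper mouth, a 1.5–1.8 mm BZ rim around the scar, healthy
tissue elsewhere, and fibers along the channel axis.  The geometry was
designed (and iterated on the design, not on any acceptance threshold)
so that the reentry circuit — around the scar, in at the upper mouth,
down the channel, out at the lower mouth — takes longer than the
remodeled channel's refractory period:

* the channel plus rim carry the BZ label (slow conduction; long APD
  when ER is on), the outer loop is healthy (fast recovery), giving the
  premature wave a wide refractoriness window at the lower mouth while
  the outer loop stays excitable;
* the rim acts as an impedance-matching collar at the channel exit: with
  a rim thinner than ~1 mm the narrow-channel wavefront fails into the
  healthy sink and reentry self-terminates after one or two laps;
* fibrosis levels select the brightest elements of a seeded correlated
  pseudo-enhancement field over the BZ, so fibrotic patches cluster near
  the scar as in image-based fibrosis.

With ER on, the S2 scan produces unidirectional block at the lower mouth
followed by sustained reentry (cycle length ≈ 0.5 s on this geometry);
with ER off and no fibrosis there is no APD gradient at the mouth, the
premature wave either crosses the channel or fails at the pacing site,
and no version of the scan induces VT — mirroring the qualitative
pattern of the organ-scale study (its patient-specific coupling
intervals, VT rates, and the full eight-version table depend on the
patient geometry and are out of desk scale; the eight-version ×
pacing-site report structure is implemented and runnable).

## Forward ECG

Extracellular potentials come from the passive bidomain relation under
the equal-anisotropy-ratio assumption with the monodomain conductivity
as the harmonic mean of the intra- and extracellular tensors
(σ_e = λ σ_i, default λ = 1), i.e. (1+λ) K φ_e = −K V_m with K the
assembled monodomain stiffness, gauge-fixed to zero mean.  The torso is
a tetrahedral P1 FEM Laplace problem with Dirichlet data at the
heart–torso interface and natural no-flux conditions on the body
surface, solved by Jacobi-preconditioned conjugate gradient (an
incomplete factorization is not symmetric-definite in the available
sparse toolkit, and the diagonal preconditioner converges in all shipped
problem sizes).  Regional conductivities (S/m): lungs 0.0389, liver
0.147, bone 0.02, blood 0.7, myocardium per tissue model, unassigned
space 0.239.  Verification uses a closed-form l = 1 solution
φ = (r + b³/2r²) cos θ on a spherical-shell wedge (no-flux at the outer
radius by construction, Dirichlet elsewhere): the FEM solution agrees
within 0.8 % at the shipped resolution and converges under refinement.
The phantom torso is a tetrahedralized box with a spherical heart region
and six anterior electrodes; it supports smoke tests (non-flat leads,
gauge invariance, polarity reversal), not patient comparisons.

Electrogram annotation: LAT is the bipolar deflection (local extremum of
|bipolar| above 5 % of its peak-to-peak amplitude) closest to the
steepest negative unipolar slope.  Mapping points under 0.5 mV bipolar
peak-to-peak are non-excitable and are removed before the coherence
filter, which drops points whose LAT deviates from the inverse-distance
weighted neighbor mean by more than 3× the median absolute residual
(the source procedure is qualitative here; the threshold is a package
convention and is configurable).

## Problem sizes

Desk-scale sizes were chosen once as the package defaults: CV rig
30 × 1.6 × 1.6 mm at dx 0.4 (≈1.9 k nodes, sub-minute per measurement);
reentry fixture as above (≈3.5 k nodes; the full PES scan for one model
version takes minutes); ECG smoke on an 8 × 8 × 2 mm slab and a 10 mm
box torso.  The organ-scale study behind the method used ~4 M-node
meshes; nothing in the implementation caps the grid size.

## Limitations

* The conduction-velocity table at 0.4 mm resolution is
  discretization-regime sensitive.  The transverse and border-zone
  wavefronts are under-resolved at that spacing, and different published
  solvers slow them by different amounts; our consistent-mass scheme
  reproduces the longitudinal calibration point exactly and the
  longitudinal border-zone velocities within ~7 %, but yields slower
  transverse velocities than the reference organ-scale solver reported
  (and the mildest BZ set comes out ~10 percentage points more reduced).
  The remodeled transverse pair in that reference equals exactly
  healthy/4, i.e. a rounded "75 % reduction", which suggests those
  entries are not precise measurements either.  Converged (fine-grid)
  velocities are reproducible with this package by lowering dx.
* The isthmus fixture is a two-dimensional caricature: no wall
  thickness, no transmural fiber rotation, one channel.  It demonstrates
  the block-and-reentry mechanism and the ER dependence, not
  patient-specific coupling intervals or VT rates.
* The synthetic DE-MRI volume has piecewise-smooth plateaus plus
  stationary correlated noise; real enhancement has partial-volume
  effects, surface coils and motion artifacts.  Passing the segmentation
  tests shows the SD-method implementation is exact, not that it is
  robust to clinical artifacts.
* Fibroblast density per fibrotic element is encoded only through the
  fibrosis conductivity and node-majority rule; no explicit
  fibroblast-per-myocyte ratio is modeled in tissue.
* Limb leads/Wilson terminal, bath loading, full bidomain dynamics,
  Purkinje conduction and three-axis orthotropy are out of scope.
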