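# Methods

## Scientific problem

Gain-of-function mutations in *KCNJ2*-encoded Kir2.1 channels (short QT
syndrome variant 3, SQT3) increase the atrial inward-rectifier current
I_K1, abbreviate repolarisation, and create a substrate for atrial
re-entrant arrhythmia.  The two mutations modelled here act differently:
D172N increases outward I_K1 between roughly −75 and −45 mV while leaving
inward rectification intact, so it accelerates terminal repolarisation and
hyperpolarises the resting potential; E299V weakens (heterozygous) or
abolishes (homozygous) rectification, so outward I_K1 flows throughout the
action potential, suppressing the plateau.  `atrikir` implements the full
chain from voltage-clamp current data to tissue-level arrhythmia markers:
rectifier fitting → single-cell action potentials → 1D/2D monodomain
tissue → re-entry quantification → conductance-scaling pharmacology.

## The I_K1 formulation

All genotypes share one chord-conductance family

    I_K1(V) = g_K1 · (V − E_K) · 2 / (1 + exp(a·(V − b)))      [pA/pF]

with conductance `g_K1` (nS/pF), rectification steepness `a` (1/mV) and
midpoint `b` (mV); `E_K` is the Nernst potassium potential computed from
the cell model's K⁺ concentrations at 37 °C (≈ −86.9 mV at K_o = 5.4 mM,
K_i = 139 mM).  The Boltzmann factor is normalised so that `a = 0` is
*exactly* the ohmic current `g_K1·(V − E_K)`, continuously in `a`; this
matters because the homozygous E299V channel is essentially ohmic over the
physiological range and parameter fitting must be able to approach that
limit smoothly.  In this parametrisation the native Courtemanche-
Ramirez-Nattel (CRN) rectifier corresponds to `(g, a, b) =
(0.045, 0.07, −80)`.

Heterozygous channel populations are represented by directly fitted
parameter sets (default).  A 50:50 WT/mutant mixture mode
(`w·I_WT + (1−w)·I_mut`) is available as a documented fallback.

Parameters are recovered from I-V data by Nelder-Mead least squares
(`fit_ik1`), bounds g ∈ [0, 1] nS/pF, a ∈ [0, 0.5] /mV, b ∈ [−120, 0] mV,
with one restart from a perturbed initial point on non-convergence.
On noiseless data from the model family the fit recovers the generating
parameters to better than 0.1%.

### Genotype fixture parameters

No published parameter table exists for this rectifier family, so
the shipped genotype parameter sets were *calibrated*: for each genotype,
(g, a, b) were optimised so that the cell model paced at 1 Hz reproduces
the reported APD90 and resting potential, subject to the qualitative
voltage-clamp phenotype of each mutation (WT and D172N forms: steep
rectification, a ≥ 0.05, outward-current peak between −70 and −50 mV;
WT-E299V: weak rectification; E299V: a = 0).  Frozen values
(g_K1 nS/pF, a 1/mV, b mV):

| genotype  | g_K1     | a        | b       |
|-----------|----------|----------|---------|
| WT        | 0.012286 | 0.052016 | −52.814 |
| WT-D172N  | 0.017238 | 0.055350 | −52.090 |
| D172N     | 0.020402 | 0.052310 | −50.990 |
| WT-E299V  | 0.014224 | 0.014990 | −33.480 |
| E299V     | 0.019050 | 0        | —       |

Four genotypes hit their APD90/RMP targets to <0.1%.  The homozygous
E299V set is a deliberate compromise: with a single ohmic conductance the
model cannot simultaneously reproduce APD90 = 125 ms and a resting
potential *depolarised* above WT (the reported −73.0 mV); the shipped
value favours APD90 (≈ 123.4 ms) and yields RMP ≈ −76.4 mV.  The reported
depolarisation is attributed to reduced outward current near −70..−80 mV,
which a one-component ohmic reconstruction cannot represent while
simultaneously carrying enough repolarising current.  This is the one
genotype-ordering property (RMP of E299V vs WT) the package knowingly does
not reproduce.

## The atrial cell model

The cell is the 1998 CRN human atrial Hodgkin-Huxley
model (12 membrane currents, two-compartment SR calcium subsystem, 21
state variables) with its native I_K1 replaced by the formulation above.
The reported biomarkers being targeted come from a further-modified
descendant of CRN whose other changes are not published; the rectifier
calibration above absorbs that difference at the level of the
biomarkers.  Two deliberate
numerical conventions:

* stimulus convention: positive amplitude depolarises (dV/dt = −I_ion +
  I_stim, currents in pA/pF); default stimulus 20 pA/pF for 2.0 ms;
* the stimulus charge is booked to the K⁺ flux, so paced limit cycles are
  charge-conserving and long runs do not drift.

Integration is Rush-Larsen (exponential) for the gating variables and
forward Euler for V and concentrations; dt = 0.005 ms for single-cell
(clamp-grade) runs, 0.02 ms in tissue.  Halving dt from 0.01 to 0.005 ms
changes APD90 at 1 Hz by < 1 ms.  Steady-state pacing uses 50 beats with
the final two beats analysed (drift < 0.5 ms, alternans flagged when the
final two APD90s differ by more than 5 ms).

Regional electrophysiology (CT, PM, PV, LA, …) is expressed as
multiplicative conductance-scaling sets relative to the baseline
right-atrial model.  The shipped factors are approximations of the
published regional gradients (crista terminalis: larger I_CaL, long APD;
pectinate muscles: slightly shorter APD; pulmonary-vein sleeves: higher
I_Kr, lower I_K1/I_CaL) — adequate for junction-dispersion and
vulnerability experiments, not a substitute for the original regional
model family.  Interventions (drug block/agonism) are multiplicative and
commute with region and genotype scalings.

## Tissue model

The monodomain equation ∂V/∂t = ∇·D∇V − (I_ion + I_stim)/C_m is solved on
node-centred voxel grids (1D strand 25 mm / dx 0.25 mm; 2D sheets;
small 3D slabs) by central differences with mirror-node no-flux
boundaries, one explicit update per step (no operator splitting).
D = 0.21 mm²/ms, with a 9-fold increase along the fibre axis where
anisotropy is enabled; fibre fields are axis-aligned.  The explicit
stability bound dt ≤ dx²/(2·Σ_axes D_ax) is enforced.  WT plane-wave CV
on the strand is 0.71 m/s at the working resolution (dx 0.25 mm,
dt 0.02 ms); CV scales as √D to within a few percent and the anisotropic
velocity ratio is √9 = 3.  Under refinement CV converges from below
(0.717 / 0.749 / 0.757 mm/ms at dx 0.25 / 0.125 / 0.0625 mm, dt
0.005 ms): the working resolution underestimates the converged CV by
~5%, which is characteristic of explicit finite differences at 0.25 mm;
all genotype comparisons are made at matched resolution, where the bias
cancels.

For speed, the tissue kernel tabulates every purely voltage-dependent
quantity (gate steady states and Rush-Larsen exponentials, g_Kur(V), the
I_Kr rectification factor, f_NaK, the Na/Ca-exchanger exponentials and
each parameter set's I_K1 conductance factor) on a 0.05 mV grid with
linear interpolation, refreshes reversal potentials every 0.2 ms
(concentrations drift far more slowly), saturates the near-step SR-release
sigmoids outside ±40 widths (error below double precision), and replaces
one per-node exponential by its third-order Taylor polynomial (truncation
error < 1e−9).  The tabulated stepper agrees with the direct-rate
single-cell stepper to better than 1 mV pointwise along a paced beat, well
under the discretisation error; the test suite checks this on a one-node,
zero-diffusion grid.  Concentrations are floored at small positive values
to keep extreme suprathreshold test stimuli (hundreds of pA/pF during
threshold bisection) from driving an Euler overshoot through zero.

## Protocols

* **APD restitution** — S1-S2: conditioning at the S1 cycle length until
  stable, one premature S2 per coupling; DI = coupling − APD90 of the last
  S1 beat; maximal slope = max forward finite difference.  APDs are
  measured from the maximum-dV/dt time (robust to stimulus artefact);
  APD90/APD50 at 90%/50% repolarisation of the amplitude.
* **ERP** — five S1 beats (2.5 mm stimulated segment) on the strand;
  bisection of the S1-S2 coupling to 1 ms; a response counts as propagated
  if the node at 16.25 mm crosses −20 mV after the S2 (−40 mV is used for
  activation *timing*, −20 mV for excitation classification).
* **CV** — activation-time difference between the quarter and
  three-quarter strand nodes (12.5 mm apart); **WL** = CV × ERP.
* **Excitation threshold** — five S1 beats at the S1-S2 interval, then a
  single-node (0.25 mm), 2 ms test stimulus whose amplitude is bisected to
  1 pA/pF; propagation criterion as for ERP.  The single-node test site
  reproduces the reported threshold scale; a 2.5 mm test segment yields
  values ≈ 4× smaller (source-sink effect).
* **Vulnerability window** — a CT|PM junction strand is conditioned from
  regional 1 Hz steady states, an S1 plane wave launched from one end, and
  a local 2.5 mm S2 applied at the junction at scanned timings; each
  timing is classified by S2-attributable activation of the 20% / 80%
  flank nodes into bidirectional block / unidirectional conduction /
  bidirectional conduction.  The window is the contiguous unidirectional
  range.  With a propagating S1 even a homogeneous strand has a finite
  window equal to the flank-to-flank conduction delay (~12 ms); an
  optional uniform whole-strand S1 removes that term and isolates the
  regional-refractoriness contribution (exactly zero for homogeneous
  tissue).
* **Cross-field initiation (2D)** — four plane-wave S1 beats at BCL
  400 ms from the left edge, then a premature S2 over the lower-left
  quadrant, at timings ERP + {5, 10, 15, 20, 25} ms on the 50 × 50 mm
  test sheet.  (On a sheet of edge L the post-ERP recovery front lies
  CV·Δt ≈ 0.7·Δt mm past the ERP line at the S2 moment; timings are kept
  proportional to the L/2 quadrant so the front stays inside it — on the
  half-size sheet the published-scale offsets of up to 80 ms would put the
  front outside the quadrant and produce plane-wave capture instead of
  wavebreak.)  S2 amplitude equals the S1 amplitude (20 pA/pF).
* **Phase-distribution initiation** — each node's full state is sampled
  from a one-cycle paced limit trajectory (256 samples at BCL 300 ms) at
  phase θ(x) = atan2(y−y₀, x−x₀) about the filament; produces one rotor of
  chosen chirality on the first rotation.
* **Tip tracking** — phase by delay embedding (τ = 5 ms) of the V movie;
  singularities by ±2π plaquette winding of wrapped phase differences;
  nearest-neighbour linking with a 2 mm/frame gate; lifespan = last frame
  with an in-domain tip; meander = convex-hull area of the dominant
  track over 1 s sliding windows, averaged.
* **Dominant frequency** — largest peak of the Hann-windowed periodogram
  of a ≥ 2 s voltage recording, searched in 0.5–20 Hz; quiescent traces
  (span < 10 mV) are reported as absent.

## Synthetic data

`make_iv_dataset` emulates steady-state voltage-clamp I-V families
(−120…+20 mV in 5 mV steps) from the genotype templates with additive
homoscedastic Gaussian noise — adequate for parameter-recovery studies,
but without the leak subtraction artefacts, series-resistance error, or
voltage-dependent noise of real patch-clamp data.  `make_ap_waveform` is
a piecewise-analytic atrial AP cycle (1.5 ms upstroke, decaying plateau,
sigmoidal terminal repolarisation to −78 mV, APD90 ≈ 255 ms at CL 1 s)
standing in for a digitised model AP; AP-clamp results with it probe the
I-V relationship along a realistic trajectory, not the exact published
waveform.  Geometries are idealised cables, two-region junctions, sheets
and slabs; the anatomically realistic 3D atria (and hence anatomical
re-entry anchoring, regional ΔAPD maps over the true geometry, and their
DF values) are deliberately out of scope, so tissue-level results are
orderings and mechanisms, not anatomical frequencies.

## Problem sizes in the shipped tests

Single-cell runs use 50 beats (dt 0.005 ms) for headline biomarkers and
15–30 beats (dt 0.01 ms) for orderings; restitution uses 10 S2 couplings;
ERP/threshold searches bisect to 1 ms / 1 pA/pF with the five-beat
conditioning computed once per rate and reused; the vulnerability scan
steps 2 ms; the 2D re-entry checks run the 50 × 50 mm sheet at dx 0.5 mm,
dt 0.02 ms with a 1.2 s (WT) / 2.1 s (D172N) observation window.  These
sizes are the package's test defaults; all protocol functions accept the
full-scale settings (100 × 100 mm, dx 0.25 mm, 5 s windows) through their
arguments.

## Known limitations

* The rectifier reconstruction is calibrated to reported biomarkers, not
  to the original (unavailable) parameter table; the E299V resting
  potential sits ≈ 3 mV below the reported value (see above).
* The cell model is baseline CRN; regional/ionic modifications beyond
  I_K1 in the modified-CRN lineage are approximated by conductance
  scalings.
  Rate adaptation at fast pacing is consequently stronger than in that
  lineage: the WT effective refractory period at BCL 300 ms is
  ≈ 260 ms here, so a 300 ms premature stimulus falls outside the WT
  refractory shoulder and the measured WT excitation threshold at
  SI = 300 ms is its diastolic value (~33 pA/pF) rather than the elevated
  refractory-shoulder value reported for the modified-CRN lineage.  The mutant
  thresholds and their ordering are reproduced.
* On the half-size (50 mm) sheet the D172N rotor wavelength (~95 mm)
  exceeds the domain, making sustainability sensitive to the S2 timing;
  see the test suite for the observed per-timing outcomes.
* No Kir2.x heteromers, no time-dependent Kir gating, no fibrosis or
  mechanical coupling; drug effects are pure conductance scalings without
  concentration-effect or state-dependent binding.
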