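# Methods

This note documents the models behind the `vsrdv` simulation, the default
study conditions, and the numerical and design choices that were genuinely
open, in enough detail to reproduce or challenge any number the package
prints.

## Digital flow phantom

The phantom emulates a silicone circle-of-Willis replica suspended in
gadolinium-doped agar and driven by a pulsatile pump.  It is built from
cylindrical vessels (straight segments, one U-bend, one bifurcation) swept
along analytic centerlines.  Within each lumen the through-plane velocity is
Poiseuille, v(r) = v_max(t)·(1 − (r/Rad)²), directed along the local
centerline tangent; v_max(t) is the vessel's peak speed times a shared
raised-cosine systolic waveform (systole occupying 30 % of the cycle on a
diastolic baseline of 20 % of peak, renormalized so the maximum over the
sampled frames is exactly 1).  Flow is conserved at the bifurcation by
construction (daughter speeds chosen so Σ v_max·Rad² matches the parent).

Default grid: 64×64×32 voxels at 0.8 mm isotropic, 10 cardiac frames.
Vessel peak speeds (100, 90, 70, 60, 53.3, 45, 40 cm/s) straddle
venc_low = 55 cm/s so that both aliased and non-aliased voxels exist;
straight centerlines pass through voxel-center rows so configured peaks are
attained exactly.  Signal magnitude: lumen 1.0, agar 0.6 (with seeded
speckle of sd 0.02), blended by partial-volume occupancy at the wall.  The
whole volume is tissue — an air shell around the block was deliberately
removed after it was found to ring Gibbs fringes (low-magnitude, high phase
noise) through the static region.  The static-tissue mask stops two voxels
short of every wall; nearer voxels are partial-volume contaminated and are
neither lumen nor "clean agar".

Eighteen analysis planes (three per major vessel, one per bifurcation
branch) are placed perpendicular to the centerlines with extent 4×radius.
Analytic plane statistics (mean = v_max/2, peak = v_max, area = π·Rad²)
serve as ground-truth oracles.

Not modeled: Womersley/CFD flow profiles, turbulence, wall motion,
off-resonance, eddy currents, Maxwell terms, motion.  Passing tests
therefore demonstrate the internal consistency of the sampling/recon/
unwrapping chain under thermal noise, not robustness to those confounds.

## Sampling design

The phase-encode plane (ky × kz) carries a centered, fully sampled
autocalibration (ACS) block and a sheared undersampling lattice: outside the
ACS bands, one of every R positions is acquired, with the lattice phase
advancing by one step per kz row and per cardiac frame, so every position is
acquired at least once in any R consecutive frames.  The lattice lives in
the region where **both** ky and kz are outside the ACS bands; the two
"cross" bands (central ky at outer kz, and vice versa) are never acquired.
This is what makes the per-frame line count match the closed form
`(Nky−ACSy)(Nkz−ACSz)/R + ACSy·ACSz` exactly (the package's acceleration
accounting is brute-force-verified against it), at the cost of a structural
low-pass: every reconstruction of this design lacks the cross bands.  Since
the Zero-Filled and Reference images share the identical support, the
comparison metrics are unaffected; absolute image fidelity is not the
purpose of the line-budget model.  R = 1 is special-cased as full sampling.

The HV mask deletes the K outermost acquired non-ACS lines per frame,
ranked by the normalized elliptical radius (2·Δky/Nky)² + (2·Δkz/Nkz)² with
a deterministic lexicographic tie-break; ACS lines are never deleted.  Two
conventions for K are supported:

* `z_budget="eq6"` (module default): K = round(z·Nky·Nkz/R), the printed
  closed form.  Under this reading z ≥ 0.6 is infeasible (K exceeds the
  removable lines) at the reference scanner geometry itself.
* `z_budget="removable"` (experiment default): K = round(z·(Lines_LV −
  ACSy·ACSz)).  Feasible for all z ∈ [0, 1), and the only reading whose
  implied scan-time saving at z = 80 % (~33 % at the reference geometry)
  approaches the protocol's reported value — so it is taken as the study
  condition.

Optional: elliptical ("cut-corner") outer-mask mode (counts then come from
mask counting, not the closed forms) and even/odd-frame alternation of the
zero-filled set.

## Acquisition model

Eight encodings per cardiac frame: reference + x/y/z flow encodes for each
of LV (venc 55 cm/s) and HV (venc 110 cm/s).  The reference phase is a fixed
first-order background field; a flow encode adds π·v_d/venc.  Because the
background phase is common to all encodings it cancels exactly in the phase
difference; optional per-encode "eddy" phase fields are available to stress
the background correction, and default to zero.  Signal = magnitude·e^{iφ}.

Coil maps are Gaussian lobes on two stacked, azimuthally staggered rings (a
head-coil-like array giving sensitivity variation along all three axes),
with mild random linear phases, normalized to unit root-sum-of-squares.
k-space is the orthonormal 3D FFT of the coil-weighted images (orthonormal
so Parseval and noise propagation are exact: white k-space noise of sd s per
component reconstructs to image noise of sd s).  i.i.d. complex Gaussian
noise is added to acquired samples only; all randomness flows through
explicit integer seeds, and a fixed seed reproduces the identical
realization at any noise scale (used by the noise calibration).

## k-t GRAPPA reconstruction

Missing lattice samples are synthesized per coil from acquired neighbours,
with one weight set per lattice phase offset p, trained by Tikhonov-
regularized least squares on the ACS block (λ = 1e-5 × the mean diagonal of
the normal matrix; at 1e-4 the ACS self-consistency residual was
regularization-dominated at ~2×10⁻³, an order above what the data support).
Source pattern for a target with phase p: for each (Δt, Δkz) in a
cross-shaped window (Δt up to ±1 for R = 2 and ±2 for R > 2, Δkz ∈ {−1,0,1},
corners of the window excluded), the one or two nearest acquired lines at
ky-rank offsets −p′ and +(R−p′) with p′ = (p+Δkz+Δt) mod R — when p′ = 0 the
co-located sample at that (Δkz, Δt) is itself acquired and is used directly.
Each source spans kx ∈ {−1, 0, 1} and all coils.  A ky-only ±1-frame kernel
was measured to amplify noise 4–8× at R = 5 (8 ring coils cannot separate
5-fold ky aliasing); with the kz-diagonal and ±2-frame sources the R = 5
noise matches R = 2, and the reconstructed R = 5 LV noise ratio (11.75 % of
venc) falls where equal-resolution in vitro protocols report it.
Calibration equations are deterministically thinned to ≤20 000 rows.
Frames are cyclic (cardiac periodicity); rank indices wrap at the band
edges.  Acquired samples are never overwritten, and HV corner-zero-filled
positions (lattice phase 0) are never synthesized — the variable-resolution
method deliberately leaves them empty.

Coil combination is conjugate-sensitivity weighting with the simulated maps
(an oracle; adaptive combination for measured data is out of scope).
Velocity: v_d = venc·angle(S_d·conj(S_ref))/π, magnitude = mean modulus over
the four encodings of the role.  Arrays are complex64 by default; passing
complex128 images propagates double precision end to end (the noiseless
round-trip tests recover velocities to 1e-6 cm/s that way).

## Dual-venc unwrapping and metrics

The substitution bands are applied exactly as printed, as open intervals
(boundary values are untouched; they have measure zero under noise).  At a
venc ratio of 2, |HV − LV| < 3·venc_low always, so the ±(3.2–4.8)·venc_low
bands can never fire; they are implemented and property-tested as dead.
The substitution bookkeeping stores the applied multiple of 2·venc_low per
direction/voxel/frame; a voxel counts as "aliased" if any direction or
frame was substituted (pooled counting, recorded in output metadata).
TPR = 100 × |ref-aliased ∩ zf-aliased ∩ ROI| / |ref-aliased ∩ ROI|, returned
as undefined-with-warning when the reference flags nothing inside the ROI.

Noise ratios are the mean |velocity| over static voxels, directions and
frames, divided by the volume's venc — venc_low for LV, venc_high for HV
and DV (a signed mean would vanish by symmetry; the mean magnitude is what
the reported in vitro ratios are consistent with).

Background phase correction fits a0 + a1x + a2y + a3z per direction over
static voxels (time-averaged by default, per-frame optionally) and subtracts
it volume-wide; degenerate static geometry raises.  PCMRA =
sqrt(meanₜ M²·(vx²+vy²+vz²)).  Plane quantification resamples velocity and
lumen mask trilinearly onto a 0.25 mm in-plane grid, takes lumen pixels at
mask ≥ 0.5, and reports the per-frame mean and the signed extremum
(largest-magnitude value, so reversing the plane normal negates both mean
and peak) of the through-plane component, plus pixel-count area.
Bland–Altman: bias, sample-sd limits of agreement, one-sample t-test of the
bias, and the regression of differences on pair means (slope and intercept
both reported, since the convention for a proportional "offset" varies).
Repeatability coefficient: 1.96 × sd of paired session differences.

## The experiment design and its conditions

For each R, one noisy acquisition is simulated at z = 0; the z > 0 HV
k-spaces are that same realization with the corner samples deleted.  Every
Zero-Filled DV (LV unwrapped with the z > 0 HV) and its Reference DV (same
LV, z = 0 HV) therefore share all LV data and noise, so the differences
isolate the HV resolution — the point of the design (an in vivo-like
variant with fresh noise per z sits behind a flag).  Study conditions:
venc 55/110 cm/s, R ∈ {2, 5}, z ∈ {0, 0.2, 0.4, 0.6, 0.8} (removable
budget), ACS 16×8 (the reference protocol's ACS fractions, ~25 %, scaled to
the 64×32 phase-encode plane), 8 coils, and k-space noise calibrated by
fixed-point iteration so the reconstructed LV static noise ratio is 10.9 %
of venc_low at R = 2 (the ratio is nearly proportional to the noise sd, so
2–3 rescalings of the same realization converge to ±0.05 points).

The angiogram mask is segmented once, from the reference dataset of the
lowest R, and applied to all datasets.  At a 10.9 % noise ratio no PCMRA
threshold separates the slow vessels from the static-background noise tail
(the background's 95th percentile exceeds the lumen median; median
filtering and hysteresis growing both fail because the reconstruction-noise
hotspots are smooth).  The physical experiment resolved this with manual
segmentation — a rater outlining vessels using anatomical knowledge.  The
simulation's stand-in for that rater is the anatomy it knows exactly: the
mask is the PCMRA threshold mask (0.15 × max) intersected with the
phantom's true lumen, and the TPR ROI is its 2-voxel ball erosion.
Without this, background false-unwraps (±2·venc_low spikes at ~0.3 % of
noise samples) dominate the extremum-based plane peaks and the agreement
statistics measure segmentation noise rather than antialiasing.

Per grid cell the runner reports the acceleration accounting, TPR,
LV/HV/DV noise ratios, per-plane statistics of the Zero-Filled DV, and
Bland–Altman agreement of the time-averaged plane mean/peak velocities
against the Reference DV.  `test_retest` runs the pipeline twice with
independent noise (same phantom and coils) and reports repeatability
coefficients across planes.

Problem sizes were chosen for a single-CPU desk run: the full grid
(2 R-values × 5 z-values, 8 encodings, 8 coils, 64×64×32×10) simulates,
reconstructs and evaluates in roughly five minutes and under 3 GB.

## Known limitations

* The cross-band structural low-pass (see Sampling design) means absolute
  image quality is below a scanner's for the same nominal R; all reported
  comparisons are internal and unaffected.
* The DV static noise ratio comes out at 5.8–5.9 % of venc_high when the LV
  is calibrated to 10.9 %, not the 5.45–5.5 % a Gaussian-velocity-noise
  model predicts.  The gap is real physics of the simulation: at the
  static-tissue SNR implied by a 10.9 % ratio (≈3.3), phase-difference
  noise has roughly twice the Gaussian tail mass, so the first substitution
  band false-fires at ~0.27 % of samples even with R = 1 fully sampled
  homogeneous noise (5.67 %), and GRAPPA g-factor structure adds the rest.
* Plane peaks are extremum statistics and remain sensitive to single-pixel
  unwrap disagreements in low-SNR rim pixels; the shared-noise design
  cancels most but not all of this.
* The synthetic phantom's vessels are analytically smooth tubes; effects of
  real lumen texture, secondary flows in bends, and segmentation
  variability on real angiograms are outside what these tests demonstrate.
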