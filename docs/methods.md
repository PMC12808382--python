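# Methods

## The measurement being modelled

Dynamic PET with [¹⁵O]H₂O measures tissue perfusion because water is freely
diffusible and inert: the one-tissue compartment model

  dC_T/dt = K1·C_a(t − Δ) − k2·C_T(t)

has influx K1 equal to perfusion (mL·cm⁻³·min⁻¹; displayed ×100 as
mL/100 cm³/min). C_a is the arterial tracer concentration, here an
image-derived input function (IDIF) from the superficial femoral artery; Δ
is the transit delay from that artery to the calf muscle. The blood volume
fraction is fixed at zero — with water's near-complete extraction in muscle
it is not separately identifiable over a 370-s scan, and no partial-volume
correction is applied anywhere, so VOI means are taken at face value.
2-tissue models are deliberately out of scope: water has no second
kinetically distinct tissue pool.

## Framing and decay correction

The acquisition is binned into 22 contiguous frames — 8×5, 3×10, 4×15,
6×30, 1×60 s (370 s total). All frame values in this package are *frame
averages* of the underlying instantaneous concentration, which is what a
reconstruction integrates; mid-time point-sampling is never assumed.

Decay correction uses the ¹⁵O physical half-life 122.24 s with reference
time = injection = scan start. For a frame (t₀, Δt) the frame-averaged
measurement is multiplied by

  F = e^{λt₀} · λΔt / (1 − e^{−λΔt}),

the reciprocal of the frame average of e^{−λt}. This is exact for activity
constant within the frame (the round-trip test asserts recovery of a
constant to 1e-9) and is the standard frame-wise correction otherwise; the
simulator applies true exponential decay on a fine grid, so the residual
within-frame mismatch between exact decay and F survives into simulated
images exactly as it does in real reconstructions.

## Synthetic lower-leg phantom

The phantom exists so that every downstream stage has exact ground truth;
anatomical realism is explicitly *not* a goal, because the analysis
consumes label volumes, not gray values. Geometry is parametric axial
cylinders on the protocol grid (1.65 × 1.65 × 1.5 mm voxels, default
64 × 64 × 272 ≈ 10.6 × 10.6 × 40.8 cm): tibia (r = 11 mm) and fibula
(r = 6 mm), a posterior muscle compartment (r = 22 mm), an anterior
compartment (r = 10 mm), and a 3-mm-radius artery standing in for the
superficial femoral artery. Landmarks default to malleolus z = 0 mm, knee
joint space z = 380 mm, arterial bifurcation z = 395 mm, so the IDIF start
plane (3 cm distal to the bifurcation) lies in-volume.

The arterial input is a peak-normalized gamma variate plus recirculation
plateau:

  C_a(t) = A(1−r)·((t−t₀)/(αβ))^α e^{α−(t−t₀)/β} + A·r·(1 − e^{−(t−t₀)/τ})

with defaults A = 60 kBq/mL, t₀ = 12 s, α = 2.5, β = 4 s (peak at
t₀ + αβ = 22 s, inside the early 5-s frames), r = 0.15, τ = 40 s — a
first-pass bolus shape typical of a 400-MBq intravenous injection reaching
a leg artery.

Tissue ground truth spans the physiologically observed calf-perfusion range
1.54–5.22 mL/100 cm³/min. Since no tissue k2 is established for this
setting, the default ties k2 to K1 through the conventional blood/tissue
partition coefficient of water in muscle, p = 0.9 mL/cm³ (k2 = K1/p); this
is a configurable assumption, not a measured value. Default arterial-to-
tissue delay is 4 s.

Noise is Poisson on pseudo-counts: expected counts per voxel and frame are
κ·C·Δt·V (κ in counts per kBq·s, C the decayed concentration, Δt the frame
duration, V the voxel volume in mL), drawn before decay correction —
mimicking the dominant count-statistics structure of dynamic PET without
modelling reconstruction. κ = 0 is exactly noiseless; the default κ = 10
yields single-voxel frame CVs of order 30–80% and VOI-level CVs of a few
percent, a regime comparable to clinical dynamic water scans. A single RNG
seed drives all draws; identical seeds give bit-identical images.

What the phantom does **not** emulate: OSEM reconstruction and its
correlated noise, attenuation/scatter, scanner PSF and time-of-flight,
spill-over between artery and background, patient motion, and anatomical
shape variability. Passing tests therefore demonstrate correctness of the
*analysis chain* under controlled conditions, not clinical performance on
patient data.

## IDIF extraction

At the frame where the artery search region's mean is maximal (first-pass
peak; ties to the earliest frame), the 4 highest-intensity voxels per
axial plane are selected over 10 consecutive planes (40 voxels), starting
at the plane nearest (bifurcation − 30 mm). The fixed mask is applied to
all frames and the plain mean is the IDIF — re-selection per frame is not
done. Equal-intensity ties break by lexicographic (x, y) voxel index so
the manual step of the clinical protocol becomes deterministic. Because
the rule takes per-plane maxima, noise biases the IDIF peak upward; this
is a property of the selection rule itself and is asserted qualitatively
in the tests rather than corrected.

## VOI construction

Coordinates: voxel (0,0,0) center at the world origin, slice k centered at
z = k·dz, z increasing foot → abdomen ("distal" = decreasing z). All
distances are Euclidean in world mm (anisotropic voxels respected), and
membership is by voxel-center inclusion — consistent with the no-PVC
analysis.

* 60% level: malleolus_z + 0.6·(knee_z − malleolus_z).
* Bone exclusion zone: voxels within 20 mm (3D Euclidean, via a sampled
  distance transform) of any bone voxel. For axially uniform bone the 3D
  and in-plane definitions coincide.
* Contour VOI: posterior-compartment label in ten consecutive 1.5-mm
  slices around the level slice, minus the bone zone. Ten slices cannot be
  symmetric about one slice; the stack is level−4 … level+5, fixed.
* Sphere VOI: union of two 7.5-mm spheres placed medially and laterally
  in the muscle at the level (analytic volume 2·(4/3)π·7.5³ = 3534.3 mm³ =
  3.5 mL; the voxelized volume is reported, not a rounded nominal figure).
  In the automated pipeline the centers sit at ±12 mm from the
  posterior-compartment centroid in the level slice; the virtual-rater
  study jitters them.

## Kinetic fitting

Basis-function method: for each delay on a 0–15 s grid (0.5-s step) and
each k2 on a 64-point log grid (0.01–3 min⁻¹), the basis
B(t) = C_a(t−Δ) ⊗ e^{−k2 t} is computed and the optimal K1 ≥ 0 is the
closed-form weighted least-squares coefficient (clipped at zero); the best
grid triple is then polished by a continuous bounded (K1, k2) optimizer at
the chosen delay. Delay stays on the grid — its reporting precision is one
grid step, and a continuous delay would buy nothing at 5-s early frames.
Weights are proportional to frame duration (longer frames integrate more
counts); uniform weighting is available for sensitivity analysis.

The convolution core interpolates the input piecewise-linearly onto a
0.05-s grid and convolves each linear segment with the exponential
*analytically* (a one-pole recursion, with a series branch for k2Δt → 0),
then resamples as frame averages via the cumulative integral; a delay is a
pure index shift of that integral. Halving the fine step changes outputs
by < 1e-6 relative. Degenerate inputs (all-zero IDIF) raise; an all-zero
tissue curve returns K1 = 0 with zero residual.

Numerical behaviour established by the tests: noiseless recovery bias
< 2% for K1 and < 5% for k2 with delay within one grid step across
K1 ∈ {1.5…5.2} × k2 ∈ {0.2, 0.4, 0.6}; at ~5% tissue-frame CV the K1 RMSE
over 50 replicates stays under 10%; the fit is invariant to a common
rescaling of both curves' concentration units. The small residual
noiseless bias (≲0.7%) comes from treating the frame-averaged IDIF as
point samples at frame mid-times — the same approximation every
clinical kinetic-modelling tool makes.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measures —
is computed from the two-way ANOVA mean squares:

  ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)),

with the McGraw–Wong F-based 95% CI (cross-checked in tests against an
independent sums-of-squares implementation and against `pingouin` to
1e-10). A constant matrix returns a flagged undefined result rather than
crashing. ICC(3,1) (consistency) is available as a labelled extra only.
Interpretation bands: poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.9 <
excellent; published band wordings overlap at the endpoints, so this
half-open/closed convention is fixed and printed. Bland–Altman limits of
agreement use 1.96 literally (not a t quantile); means are reported with
t-distribution 95% CIs.

## Virtual rater study

Ten legs are simulated with posterior K1 evenly spaced over
1.54–5.22 mL/100 cm³/min; each leg's single noisy scan is then analyzed by
2 raters × 2 sessions. Rater behaviour is placement jitter only — sphere
centers ~ N(0, 1 mm) per coordinate, contour dilated/eroded in-plane by
−1…+1 morphological steps, IDIF start plane shifted by −1…+1 slices —
because the raters in the emulated design re-read the *same* acquisition.
Intrarater ICC is computed per rater from its two sessions; interrater ICC
for every session pairing across raters (all pairings are reported, since
pooled vs paired conventions differ between studies). Each comparison also
carries a Bland–Altman summary. All perturbations are seeded per
rater-session cell, so the study is bit-reproducible.

With these defaults both VOI methods land above ICC 0.9 with biases
statistically indistinguishable from zero — the reliability regime the
protocol was designed for. This mirrors the qualitative clinical finding;
it cannot validate it, since the phantom omits the anatomy- and
motion-driven variability a real rater faces.

## Problem sizes and runtime choices

Defaults were chosen so a full run is comfortable on a laptop core: the
phantom grid is 64 × 64 × 272 (a 10.6-cm in-plane field is enough for a
calf cross-section; 41 cm axially covers malleolus to bifurcation
landmark), the noisy-recovery experiment uses 50 replicates, and the
reproducibility study 10 legs × 4 rater-sessions × 2 VOI methods. The
acceptance script completes in well under two minutes; the test suite in
about one.

## Known limitations

* No reconstruction physics; noise is independent Poisson per voxel, while
  real OSEM noise is spatially correlated — VOI-level CVs are therefore
  optimistic for equal κ.
* The IDIF is taken at face value: no spill-over/partial-volume recovery,
  so its max-selection peak bias propagates into a small K1 underestimate
  at high noise (visible in the virtual study's contour-vs-truth offsets).
* k2 defaults derive from a partition-coefficient convention, not from
  measured muscle data; studies of diseased muscle may need other values.
* Delay is resolved only to the 0.5-s grid.
* The contour/sphere placement automation replaces human anatomical
  judgement; jitter magnitudes are plausible, not calibrated to observer
  data.
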