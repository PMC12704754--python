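# Methods

`spcold` implements the analysis chain of single-particle cryogenic light
microscopy (spCryo-LM): resolving the positions of a handful of
fluorophores attached to one rigid particle — an oligomeric membrane
protein, a DNA-origami ruler — far below the diffraction limit, and
assembling many such 2D projections into a 3D structure.  The package
also contains a synthetic microscope that generates two-channel image
stacks with the statistical structure the analysis assumes, so every
stage can be validated against known ground truth without experimental
data.

## Physical model

**Polarization splitting.**  A fluorophore frozen in vitreous ice keeps a
fixed transition dipole.  Its emission, split by a polarizing beam
splitter onto two cameras, arrives as Ix ∝ I cos²θ and Iy ∝ I sin²θ,
where θ ∈ [0°, 90°] is the in-plane dipole angle.  The axial dipole
component is largely rejected by the NA-0.9 objective and is modeled as a
brightness factor |d_xy|² only; dipole-orientation-dependent PSF shapes
are not modeled, because dim (axially oriented) emitters are removed by
the brightness filter that the analysis applies anyway.

**Angle estimation.**  The default estimator inverts the splitting
exactly: θ = arctan √(Iy/Ix).  The literal intensity-ratio form
θ = arctan(Iy/Ix) is available behind `estimator="ratio"`; it does not
invert the cos²/sin² law (a dipole at 30° yields 18.4°) and is retained
only for comparison.  This choice makes the simulator/analyzer round
trip self-consistent.

**PSF and camera.**  Isotropic 2D Gaussian PSF with σ = 0.21 λ/NA
(≈150 nm at 645 nm / NA 0.9), pixel-integrated via erf differences;
unit camera gain, Poisson shot noise, flat background (default
0.3 photons/px/frame — the signal-dominated regime of clean vitreous
ice, chosen so that single-molecule polarization histograms remain
narrow, as observed in this kind of experiment).  Coordinates are nm,
x right / y up, pixel edges at integer multiples of the pixel size;
a position of (k+0.5) px is the center of pixel k.

**Blinking.**  On-times follow a Pareto power law (exponent α_on, scale
set so the median matches the preset); off-times follow either a power
law or a 3-component exponential mixture spanning three decades, scaled
to the target off median.  The canonical cryogenic (8 K) preset uses
median on 0.1 s / median off 3.0 s — the published quantity is their
ratio (~30); the split itself is a modeling choice — α_on = 2.95,
5,000 photons/s while on, and a constant-hazard photobleaching process
calibrated to 92% survival at 10 min.  Ambient (ART) uses α_on = 2.1 and
a power-law off-time with exponent 1.93.  The photon budget implied by
these numbers (~10⁵ detected photons in 10 min) is smaller than the
>10⁶ sometimes quoted for such experiments; the photon rate is exposed
as a preset knob rather than resolved here.

## Trace analysis

**On/off segmentation.**  Per-trace threshold at the off level plus 3
robust SD (median / MAD of the whole trace — valid because the off state
dominates at off-on ratios ≫ 1), with single-frame hysteresis.  Boundary
dwells are flagged censored and excluded from medians.  The dwell-time
fits are the continuous power-law MLE α̂ = 1 + n / Σ ln(xᵢ/xmin) (xmin
defaults to the 14 ms frame time, the shortest observable dwell) and an
EM-fitted exponential mixture with the component count chosen by BIC.

**Polarization states.**  The angle series of one spot is clustered into
states by a divisive hierarchy (exact 1D 2-means cuts), each candidate
state count refined by a 1D Gaussian-mixture EM, the count selected at
the global BIC minimum, followed by an agglomerative merge of states
closer than 2× the pooled SD.  Two deliberate deviations from a plain
"split while BIC improves" scheme, both forced by measurement:

* hard-assignment BIC over-splits structurally (the two halves of a
  single Gaussian have ≈0.6× its SD, so a split always "improves" the
  naive score); the EM mixture likelihood does not have this defect;
* image-derived traces are clustered per *blink event* (run of
  consecutive on-frames, gaps ≤ 2 frames bridged) rather than per frame,
  and in the channel-fraction domain f = Iy/(Ix+Iy) = sin²θ rather than
  in angle.  Pooling an event's photons reduces the angle noise by
  ≈√(event length), and f-space avoids the shot-noise blow-up of θ near
  0° and 90° (dθ/df diverges there), which otherwise fuses boundary
  states and creates spurious clusters pinned at exactly 0°/90°.

**Brightness band.**  Before clustering, on-frames outside a brightness
band are dropped: the dimmest 40% (dipole-bias mitigation and angle
noise) and frames brighter than 1.6× the median on level (two emitters
on simultaneously).  The exact cutoffs are package choices; the analysis
is insensitive to ±10% changes.

**Frame recruitment for localization.**  States are fitted on the
brightness-filtered trace, then `extend_assignment` transfers them to
the full set of on-frames so localization can use every event.  Two
consistency gates guard against contamination from overlapping
emitters: blink events farther than 3 robust SD from their state's
channel fraction are discarded, as are individual frames whose own
channel fraction contradicts the event state by more than 0.18; the
position aggregator additionally trims events beyond 4 robust SD of
the median position.

## Localization

Each selected frame of each state is fit by maximum likelihood
(2D pixel-integrated Gaussian, Poisson noise, known σ, free position /
photons / flat background).  A state's fluorophore position is the
photon-weighted mean of its events with weighted-SEM precision per axis;
the combined precision is √((σx²+σy²)/2).  States are capped at 200
events (≈1 nm precision is already reached; more fitting buys little)
and states whose aggregated precision exceeds 3 nm are discarded as
spurious.  Particles must show ≥3 polarization states within a maximum
pairwise extent of 10 nm — the filter used to select intact
ring-shaped oligomers.  The propagated distance error between two
fluorophores is √(σ₁²+σ₂²); the larger experiment-reported mapping from
0.7 nm precision to 1.8 nm distance uncertainty is not reproducible from
this formula and is treated as an open discrepancy.

## Projection geometry

A segment of true length d observed at a uniform random 3D orientation
projects to length r with density f(r) = r / (d √(d²−r²)) on (0, d).
With localization noise the density is numerically convolved with a
Gaussian of SD σ, folded at r = 0 (so it stays normalized and tends to a
half-Gaussian as d → 0).  The (d, σ) fit is by maximum likelihood with a
profile-likelihood CI for d.  The Gaussian-smearing model slightly
mis-states endpoint noise (which is Rician in the distance); the
resulting bias is <0.1 nm at the scales used here.

Labeling classes of a partially labeled n-ring are enumerated by brute
force over all C(n, k) subsets grouped under the dihedral group; for the
3-of-7 heptamer this yields 4 classes with gap multisets {1,1,5},
{1,2,4}, {1,3,3}, {2,2,3} and side lengths drawn from {3.5, 6.31,
7.86} nm at 3.5 nm protomer spacing.  The per-particle maximum projected
side concentrates near the longest true side (an equilateral triangle of
side d can never project its longest side below (√3/2) d); both the
per-particle maximum and the pooled-side histograms are produced, since
either may underlie a published peak structure.

## Classification and 3D reconstruction

**Matching.**  A particle is compared against projection banks of each
labeling class (Fibonacci orientation grid; in-plane rotation,
reflection and point correspondence solved at match time — exhaustively
for ≤4 points, by ICP/Hungarian above).  The score is
exp(−RMSD²/(2σ_s²)) ∈ [0, 1]; σ_s defaults to 2× the median combined
localization precision so that a statistically perfect match scores
≈0.9 rather than ≈0.6 (the RMSD of a correct 3-point match carries
≈1 residual degree of freedom).  Classes are *ranked* by the
maximum-a-posteriori orientation (geometric likelihood × a Gaussian
prior on out-of-plane tilt, default SD 15°): without the prior a
strongly tilted large triangle projects exactly onto a flatter small
one and the classes are not mutually identifiable.  A particle is
assigned only if the winner's geometric score exceeds 0.8; ties stay
unassigned.  At 0.7 nm noise the 4-class problem is intrinsically
overlapping (adjacent classes differ by one side of 1.5 nm against
~1 nm side jitter); accuracy is ≈70–75% there and ≥85% once the noise
is ≤0.35 nm.  The tilt-limited template bank (default 35°) reflects the
membrane-embedded sample.

**Orientation estimation.**  Simulated annealing over SO(3) of the
corresponded RMSD between the projected model and the particle
(Hungarian correspondence per evaluation; reflection is reachable inside
SO(3) as viewing from the far side), multi-restart, exponential cooling,
followed by a Nelder-Mead polish.  Out-of-plane tilt is reported in
[0°, 90°]; near-planar particles at finite noise live in a flat valley
of width ≈√(2σ/R) in tilt, so a few degrees of wander there is
expected.

**Class reconstruction.**  Blob centers start from an isotropic 3D
Gaussian draw (no symmetry imposed) and co-evolve with per-particle
orientations: each sweep runs a short annealing pass per particle (the
proposal temperature cools across sweeps from 60° to 1.5°, so
orientations stay mobile while the map is crude) and then updates the
blob centers by exact least squares given orientations and
correspondences, accepted only if the mean objective decreases — the
recorded objective is non-increasing by construction.  Several
independent initializations run a short pilot and the best continues.
Two debiasing steps follow, because point-estimate orientations absorb
noise and demonstrably contract/thicken the structure (a planar
ground-truth ring acquires ≈1.7 nm of spurious depth without them):

1. EM-style passes that re-estimate the blob centers averaged over
   Metropolis samples of each particle's orientation posterior (energy =
   residual sum over 2σ², σ from the known or residual-estimated noise),
   re-anchoring the point orientations after each pass;
2. a global scale calibration against the unbiased projected-distance
   statistic E[r²] = f·d² + 4σ² (f = 2/3 for uniform orientations; for
   other priors the factor can be supplied, e.g. computed by Monte Carlo
   for the membrane tilt prior).

For final maps, `reconstruct_class_consensus` averages several
independent runs after rigid alignment; the runs share the signal but
not the optimizer noise, which measurably stabilizes the blob centers.
Residual caveats: with 50 particles at 0.7 nm noise the per-blob error
is ≈0.5 nm, and the median nearest-neighbour distance between recovered
blob centers is biased a few percent *low* purely by the min() statistic
over noisy centers (even with exactly known orientations it evaluates to
≈3.37 nm for a 3.5 nm ring at this particle count).  Depth degeneracy
(all views near-parallel) is flagged via the conditioning of the stacked
projection rows.

**Merging and FSC.**  Class reconstructions are fit rigidly (rotation,
translation, optional reflection; best site subset and correspondence by
exhaustive search) into the accessible-volume site model and averaged
per site.  Resolution is assessed by Fourier shell correlation between
voxelized half-set maps against the half-bit information threshold
T(n) = (0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n); half-sets are
random 50/50 particle splits refined independently (gold standard).
Blob maps are voxelized (0.1 nm default) only for FSC and MRC export;
MRC/CCP4 I/O goes through gemmi with header lengths in Å.

## Synthetic data: what it does and does not emulate

The simulator reproduces: fixed dipoles at uniform random 3D
orientations (or a membrane prior with half-normal tilt), cos²/sin²
channel splitting, heavy-tailed blinking with off-on ratio 30, rare
photobleaching, Gaussian PSF rendering with Poisson noise, uniform
background.  It does not emulate: drift, camera read noise or gain
structure, dipole-dependent PSF distortion, spectral diffusion,
non-uniform illumination, or sample heterogeneity in photon rate.
Passing tests therefore demonstrate the correctness and statistical
calibration of the algorithms under the stated model, not robustness to
every instrumental artifact of a real microscope.

## Problem sizes

The test suite runs everything at desk scale: hundreds of blinking
traces where distribution recovery is asserted, 10⁴ samples for
power-law MLE checks, 50-particle reconstructions for structure
recovery, ~10-minute-equivalent recordings (42,000 frames) for the
image-level end-to-end check with 5 accepted particles.  These sizes
were chosen so each statistical assertion sits several standard errors
away from its pass boundary while the whole suite stays interactive.
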