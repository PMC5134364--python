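# Methods

This note documents the models, defaults and numerical choices behind
`groupvar`, and what its green tests do and do not establish.

## The phenomenon under study

A study-specific normalization template is the (iterated) mean of the very
tissue maps being normalized, so each subject's final normalized tissue map
(FINTM) is a function of the whole group. The package measures that
dependence: hold a few *constant subjects* fixed, vary the rest of the
group across runs according to a protocol, rebuild the template per run
from scratch, and compute the across-run voxel-wise SD of the constant
subjects' normalized GM.

## Synthetic cohort

Each phantom is built in a canonical frame and then perturbed:

1. **Base geometry** — central CSF ventricle (disc), WM body, outer GM
   cortical ribbon, on a 96×96 lattice at 1 mm spacing by default (the
   interface is dimension-agnostic; small 3-D grids work unchanged).
2. **Subject-unique folding** — the ribbon boundary radius is perturbed by
   two seeded sinusoids with amplitude 1.5–3.0 voxels, integer angular
   frequency 5–9 and uniform phase. Phase randomness makes every subject's
   "gyral" pattern unique, which is exactly the feature group templates
   average away — it is the dominant source of inter-subject variance.
3. **Age effects** — ribbon thickness decreases at 0.12 voxels/year from
   7.0 voxels at age 10.5, and the ventricle radius grows at 0.18
   voxels/year from 5.0 voxels, emulating cortical thinning and
   ventricular dilation over the 10.5–29 y range. Ages are uniform within
   the configured bands; case ages are jittered off their matched
   control's by at most 0.3 y, so nearest-age pairing recovers the match.
4. **Diagnosis effect** — case subjects receive focal *negative* GM deltas
   (default magnitude 0.15) at two fixed angular positions on the inner
   GM/WM interface, as Gaussian blobs (sigma 1.5 voxels) truncated at 3
   sigma, with ±1 voxel positional jitter per subject. Two deliberate
   choices: deltas are negative because positive deltas inside the
   near-saturated ribbon would be clipped away; and loci sit on the tissue
   interface because a gradient-based matching term is *provably blind* to
   an intensity dent in a flat region (the demons force is diff·∇I, and
   ∇I ≈ 0 mid-ribbon) — concentration effects at tissue boundaries are
   also where VBM case-control findings live in practice.
5. **Affine jitter and partial-volume blur** — a small random rotation
   (±2°), translation (±1 voxel) and scale (±2%) followed by a 0.8-voxel
   Gaussian blur, then clipping to [0, 1] and renormalization so
   gm+wm+csf ≤ 1 everywhere.

Determinism: every stochastic step draws from substreams of an explicit
seed (folding, affine, diagnosis are independent substreams, so a
control/case pair sharing a seed differs only by the diagnosis effect);
per-subject seeds derive from the cohort master seed via `SeedSequence`.

Magnitude calibration: the age and diagnosis defaults were set once so
that the resampling experiments produce mean masked SD summaries in the
0.01–0.08 range — the order of magnitude seen in real template-driven
pipelines — and were not adjusted afterwards.

## Registration engine

DARTEL-style groupwise registration is stood in for by stationary-velocity
log-demons: the subject→template match is a velocity field v whose
exponential (scaling and squaring, K = 6) is a diffeomorphism; per
iteration a demons force from the multichannel (GM+WM) SSD gradient is
smoothed with a fluid kernel (sigma 1.0 voxel), scaled by 0.4 and added to
v, which is then smoothed with a diffusion kernel (sigma 1.0). Updates
that would raise the SSD are rejected with step halving (three consecutive
rejections stop the fit), making "registration never increases SSD" a
literal guarantee rather than a tendency. Defaults: 30 iterations
(library), 12 (scaled experiment suites).

Numerical choices:

- Deformations map template coordinates to source coordinates (pull-back);
  images are resampled with linear interpolation, zero-filled outside the
  lattice, and clipped to [0, 1]. Displacement fields are extended by
  nearest-edge values instead, since a displacement has no natural zero
  background.
- Jacobian determinants use `np.gradient` (central differences in the
  interior, one-sided at the boundary).
- Scaling-and-squaring with linear interpolation satisfies the inverse-
  consistency oracle (exp(v)∘exp(−v) within 0.1 voxel of identity) for
  smooth fields with max norm ≤ 4 voxels *provided* the field is genuinely
  smooth (displacement gradient ≲ 0.35) and vanishes near the lattice
  boundary; fields approaching the folding threshold or extrapolated at
  the edge degrade to ~0.3 voxel. The accuracy of the integrator itself
  was checked against a 64-step RK4 flow (agreement to ~5e-3 voxels).

## Template construction and normalization

The template starts as the voxel-wise mean of the raw maps; each outer
iteration (default 6; 4 in the scaled suites) re-registers every subject
(warm-started) and re-averages the warped maps. Mean absolute template
change per iteration is recorded; it decreases on default cohorts, which
is the operational reading of the template growing "crisper" — no
sharpening step is applied.

Normalization warps each tissue map through exp(v), optionally multiplies
by the Jacobian determinant of the same pull-back map (the convention
under which warp+modulate conserves total tissue mass — verified to 1% by
the change-of-variables oracle), then smooths with sigma =
FWHM/(2√(2 ln 2)) per axis, converted to voxels via the spacing.
Smoothing uses reflective boundaries: constants are exactly invariant, and
for interior-supported maps (phantoms keep background margins wider than
the kernel truncation radius) reflection is numerically identical to zero
padding, so interior mass is preserved.

## Experiment protocols and statistics

E1: 20 runs × 15 controls (3 constant + 12 drawn uniformly without
replacement from the remaining 21). E2: 15 runs × 15; constants are the
three youngest controls; the 12 varying members slide up the age-sorted
pool in steps of 3. E3: 20 runs × 24; starting from 20 varying controls +
1 case, each run swaps one more randomly chosen control for its
nearest-age case. E4: one run of all 48, every subject normalized.
E5/E6: E2's runs re-normalized without modulation / at 4 and 8 mm.

Variability statistics use the sample SD (n−1); the analysis mask is
*mean* GM across runs > 0.1 (a per-run mask would make the domain depend
on run order); the SD histogram uses 0.002-wide bins; the sorted profile
samples every 100th mask voxel in ascending mean order. Identical runs
yield exactly zero SD (the ~1e-16 two-pass residue is cleared where the
across-run spread is zero). Age comparisons use the pooled-variance
two-sample t-test (Welch via flag); degenerate zero-variance equal-mean
inputs return t = 0, p = 1. Group differences report mean(A)−mean(B) per
masked voxel with |diff| > 0.05 and > 0.1 exceedance fractions.

## What the synthetic world does and does not establish

On the default cohort at desk scale (seed 11; 12 demons iterations, 4
outer stages; E1 at 10 runs, E2 at 15, E3 at 15):

- Identical groups reproduce FINTMs bit-for-bit (SD ≡ 0); changing a
  single non-constant group member produces nonzero SD — the core
  template-dependence phenomenon.
- Sliding the age window dominates: mean masked SD ≈ 0.037–0.039 versus
  ≈ 0.024 for the similar-demographics baseline.
- Skipping modulation lowers variability, and variability decreases
  monotonically as the kernel widens (4 mm > 6 mm > 8 mm), matching the
  qualitative findings on real data.
- The case/control ratio sweep (E3 ≈ 0.015) lands *below* the baseline
  here, unlike on real cohorts. This is a structural property of the
  stated synthetic world, quantified in detail during development: a
  maximal in-contract focal diagnosis effect shifts a fully case-loaded
  template by ≤ 0.08 GM locally, the constant subject's modulated,
  6-mm-smoothed FINTM responds to even that by ≤ 0.01 (the kernel alone
  averages a 1.5-voxel feature an order of magnitude down), and only the
  across-run *variation* of the case fraction (~13% of full strength)
  enters the SD — a contribution of ~1e-4 against a resampling-churn
  baseline of ~0.02. Reproducing the real-data ordering would require
  diffuse case-control anatomy differences, which the localized-deltas
  phantom model intentionally excludes. Green tests here therefore
  establish the machinery and the age/modulation/smoothing findings, not
  the diagnosis-ratio finding.

## Known limitations

- 2-D phantoms by default; 3-D is supported but untuned.
- No acquisition physics, no segmentation errors, no affine/MNI stage.
- The demons engine makes no attempt to match SPM/DARTEL numerics or its
  decreasing-regularization schedule; absolute SD magnitudes are
  configuration-dependent and only orderings and invariants are
  interpreted.
- Subject-unique folding uses low-order sinusoids, far simpler than real
  sulcal geometry; inter-subject variance is correspondingly structured.
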