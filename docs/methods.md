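# Methods

`dbsmap` re-implements, end to end on synthetic data with planted ground
truth, the analysis chain used to map where and through which brain networks
pallidal deep brain stimulation (DBS) helps children with dystonia: binary
stimulation volumes from a simplified electric-field model, an
improvement-weighted voxel-wise sweetspot statistic with permutation
validation, a normative resting-state functional connectome, and a
whole-brain R-map network model.

## Spatial model

All maps are 3-D grids with a NIfTI voxel-to-world affine (world units mm,
0-based voxel indices). The canonical cohort grid is 1 mm isotropic with a
96 × 120 × 96 mm extent centred so the mid-sagittal plane x = 0 is a voxel
column — left/right mirror symmetry is then exact, which the phantom atlas
tests rely on. 1 mm matches the resolution of the pediatric template spaces such
analyses are run in; a 2 mm grid is available for fast tests
but quantizes 2–3.5 mm stimulation-volume radii into a handful of voxels.
Resampling is nearest-neighbour for masks (value-set preserving) and
trilinear otherwise; out-of-footprint voxels fill with 0 so masks stay
binary.

## Stimulation volumes

The tetrahedral-mesh finite-element field model used by clinical tools is
replaced by an
analytic source model; the scientific contract retained is the thresholding
rule, not the mesh machinery. Each active contact is a spherical source in
a uniform medium of conductivity σ = 0.14 S/m:

* current mode: |E|(r) = I / (4πσr²), with I in mA and r in mm this is
  directly in V/mm;
* voltage mode: |E|(r) = V·r₀/r², the field of a sphere of radius r₀
  (default 0.635 mm, a typical DBS contact radius) held at potential V.

Multi-contact fields superpose **vectorially** with polarity signs before
the magnitude is taken; inside a contact sphere the magnitude is held at
its surface value (the voxel exactly on a centre, where the radial
direction is undefined, is set to the clamped surface magnitude). The
stimulation volume is the set of voxels with |E| **strictly** above
0.2 V/mm; a voxel at exactly 0.2 V/mm is excluded ("above" read strictly).
Bilateral volumes are voxel-wise unions.

The test oracle is a brute-force finite-difference Laplace solve (7-point
stencil, conjugate gradients) with constant potential on the voxelized
contact and a grounded grid boundary. Two numerical points: (1) the
voxelized sphere's effective electrostatic radius differs from the nominal
radius by O(spacing), so the comparison is normalized by the FD solution's
own measured source current (discrete flux through the contact interface) —
this tests the 1/r² physics rather than the staircase; (2) the grounded
box is not the infinite medium, and near the boundary the aspherical
correction dominates, so agreement (within 5 %) is asserted between twice
the contact radius and half the box half-width, where the correction's
gradient is still negligible (it vanishes at the centre by symmetry).

## Sweetspot statistic (T-model)

Coverage(v) counts the cohort stimulation volumes containing voxel v. A
voxel enters the model iff coverage is **strictly** greater than 20 % of
the cohort (for 20 patients: n > 4). This follows the stricter of the two common
phrasings of the rule; the alternative ("at least 20 %") differs
only at the exact boundary. At included voxels a one-sample t-statistic is
computed over the improvements of the covering patients **only** —
non-coverage is missing data, not an implicit zero, otherwise the coverage
gate would serve no statistical purpose. Degenerate samples (zero variance)
map to t = 0 when the mean is 0, otherwise to a signed 1e6 sentinel.
Excluded voxels carry NaN. Improvements are the signed percentages
100·(pre − post)/pre, negative for worseners, uncapped.

Validation correlates each patient's sum of t-scores over the voxels their
volume overlaps (excluded voxels contribute 0) with improvement. The
centre of gravity is the t-weighted centroid over included voxels with
positive t, optionally thresholded and optionally restricted to a region
mask. With bilateral stimulation the t-map is near mirror-symmetric, so
the reported COG is evaluated per hemisphere (clinical sweetspot reports likewise
quote a single per-structure COG for a bilateral therapy); the default
report uses the upper quartile of positive t as threshold.

## Permutation validation and circularity

Both validations (sweetspot overlap and network similarity) correlate an
**in-sample** quantity with improvement: the t-map and the R-map are fitted
on the very improvements being tested. Permuting improvements while keeping
the fitted map fixed is therefore radically anticonservative — measured
type-I error at α = 0.05 is 0.90 (sweetspot) and ≈ 1.0 (network) on null
cohorts. The package's default permutation scheme **re-fits the map under
every permutation** before scoring; voxel inclusion (coverage gate,
nonzero-variance gate) is permutation-invariant, so only the map values are
refitted. Measured type-I error is then 0.027 / 0.047, within the
calibration band. The fixed-map variant remains available
(`refit=False`) and a test documents its anticonservatism.

p-values are one-sided (positive alternative: higher overlap/similarity
predicts higher improvement, the direction of the scientific hypothesis)
with the add-one rule p = (1 + #{null ≥ observed})/(1 + n_perm), so p is
never zero; permutations are independent uniform shuffles, seeded.

## Connectome assembly

Per-subject order: motion QC → motion regression → spatial smoothing →
band-pass → nuisance regression → matrix extraction.

* Framewise displacement follows the Power convention: sum of absolute
  backward differences of the three translations plus 50 mm times the three
  rotation differences (radians → arc length); FD of the first volume is 0.
  A subject is excluded iff FD exceeds 0.5 mm in **strictly more than**
  half of the volumes (both inequalities strict).
* Motion regression removes an intercept, a linear trend and the 6 motion
  parameters per voxel by OLS (residual + voxel mean); rank-deficient
  designs are handled by least squares with a warning. Motion-parameter
  derivatives/expansions are not used.
* Smoothing is a per-volume 3-D Gaussian with FWHM 6 mm, converted per axis
  to voxels via the affine spacings (σ = FWHM/√(8 ln 2)).
* The temporal filter is a second-order Butterworth band-pass 0.01–0.08 Hz
  applied forward-backward (zero phase, filtfilt). The printed cutoffs are
  the −3 dB points of the **single-pass** design; the zero-phase
  application squares the magnitude response (−6 dB at the cutoffs), which
  is the standard trade-off and is what the empirical cutoff measurement
  (`measure_filter_cutoff`) characterizes on the single-pass form.
* Nuisance regression removes the mean CSF and white-matter courses and,
  by default, the global (brain-mask) mean, after filtering — mirroring the
  stated order of the emulated pipeline; the regressor-vs-filter mismatch
  that order implies is noted, not "fixed".
* The matrix store is in-mask voxels × volumes in x-fastest raster order,
  with the voxel index recorded, so matrix ↔ volume round trips are exact.

## Network mapping

A patient's fingerprint is built by correlating the seed-average BOLD
course (seed = the bilateral stimulation volume on the connectome grid)
with every in-mask voxel in every connectome subject, then **averaging the
r-maps across subjects and Fisher-Z transforming the mean** — the
documented order of the emulated analysis, kept as the default even though
Z-then-average is the more common convention (both are available).
Constant voxel courses get r = 0 rather than NaN. The R-map correlates
fingerprint values with improvement voxel-wise across patients; voxels
with zero across-patient variance are excluded. Spatial similarity is the
Pearson correlation between a fingerprint and the R-map over jointly
included voxels (whole brain mask; no gray-matter restriction, since the emulated
procedure states none). Leave-one-out fitting is deliberately
not the default — the in-sample design plus refit
permutation keeps the emulated logic with a calibrated null.

## Synthetic world: what it emulates and what it does not

**Phantom atlas** — bilateral ellipsoidal stand-ins for the GPi (target)
and GPe (lateral neighbor) at pallidal coordinates (±21, −7, −5) mm,
mirror-exact across x = 0.

**DBS cohort** — one active contact per hemisphere, placed at the target
centroid with isotropic 0.5 mm Gaussian scatter (a well-executed
stereotactic series); one current amplitude per patient, uniform on
1.5–4.5 mA, shared by both hemispheres (bilaterally symmetric programming,
the usual practice in pediatric pallidal DBS). Improvement is
max_improvement (70 %) × the fraction of a planted 4 mm sphere at the
right target centroid covered by the patient's bilateral stimulation
volume, plus N(0, noise_sd²) noise (default 15 %, never clipped — the
statistics must tolerate worseners). The radius/gain pair is calibrated to
the outcome spread reported for real pediatric pallidal-DBS cohorts (mean
improvement ≈ 24 %): stimulation-volume
radii of 2.1–3.6 mm against a 4 mm sphere give noiseless improvements
averaging ≈ 25–30 %. At noise 0 the improvement is an exact deterministic
function of coverage, which the parameter-recovery tests exploit.

Design rationale (fixed once, after a documented design study): the
outcome driver is stimulation **intensity** — stimulation volumes grow as
nested balls around an accurately-targeted contact, so the sum-of-t
overlap score and the planted improvement are monotone in the same latent
variable and the validation correlation is high at n = 20. Wider placement
scatter or independent per-side amplitudes make the in-sample validation
correlation drop toward the 0.4–0.8 range (instructively, the range real
cohorts report) because the score picks up placement noise that
the improvement model does not share; the package keeps the identifiable
world as the default so that a failed recovery test signals a code defect,
not generator luck. A consequence of symmetric programming is perfect
left/right collinearity: the hemispheres are statistically
indistinguishable, the t-map is near mirror-symmetric, and the COG is
meaningful only per hemisphere.

**Connectome** — nested-ellipsoid tissue compartments (CSF core, white
shell, gray rind inside a brain ellipsoid), up to five Gaussian network
blobs (σ = 8 mm, peak 1) in the gray rind with smooth (Gaussian-filtered
white noise) latent courses that survive the 0.01–0.08 Hz band; CSF, WM
and global nuisance courses injected into their compartments; a small
motion-coupled signal; white voxel noise (SNR ≈ 1 per voxel before
smoothing). Motion traces give violators FD > 0.5 mm jumps in 60 % of
volumes and guarantee non-violators stay below 0.18 mm. Defaults mirror the scale of a
real normative cohort: 107 subjects, 7 violators, 180 volumes at
TR = 2 s (desk-scale runs use 20 subjects).

Not emulated: anatomy, hemodynamics, scanner drift/spike artifacts,
registration error, partial-volume effects. A green planted-truth test
therefore establishes that the *statistical machinery* recovers a known
signal through the full preprocessing chain — not that the pipeline is
robust to real-data artifacts.

## Numerical choices

* Strict inequalities at every published boundary (0.2 V/mm, 20 %
  coverage, 0.5 mm FD, 50 % of volumes), each pinned by a test.
* Fisher Z clamps |r| ≥ 1 to ±(1 − 1e−7) with a warning instead of ±∞.
* Zero-variance correlations error at the API surface (`pearson_r`) but
  map to defined values where a voxel map must stay total (seed
  fingerprints: r = 0; R-map: voxel excluded).
* All generators and permutation engines take explicit seeds;
  `numpy.random.default_rng` throughout, per-subject streams derived as
  `default_rng([seed, tag, index])` so subjects are independent of
  generation order.

## Known limitations

* The analytic field model ignores tissue heterogeneity, anisotropy,
  encapsulation and directional leads; it is a stand-in that preserves the
  thresholding contract only.
* The refit permutation corrects calibration but not the in-sample
  optimism of the *observed* correlation; out-of-sample validation (e.g.
  leave-one-out) is available but off by default to keep the emulated
  in-sample design.
* The connectome matrix store keeps one dense matrix per subject in
  memory; at the full 107-subject, 1 mm scale this would need a chunked
  store, which is out of scope at desk scale.
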