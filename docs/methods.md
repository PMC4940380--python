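# Methods

`thalatrack` implements a complete connectivity-based targeting analysis for
functional neurosurgery planning — probabilistic tractography from thalamic
and cerebellar seeds, percentile thresholding of connectivity maps into
candidate target volumes, consensus optimisation of the threshold, and a
decomposition of target variability into inter-subject and inter-scanner
components — together with a synthetic phantom generator that provides the
multi-subject, multi-scanner data the analysis needs, with known ground
truth.

## The phantom

Real inputs for this kind of analysis are co-registered diffusion MRI
acquisitions: per-voxel fibre-orientation fields plus label masks for the
thalamus, its nuclei, cortical targets and cerebellar structures.  The
phantom builds a stylised but topologically faithful stand-in from analytic
primitives on a configurable voxel grid (default 48^3 at 2 mm, RAS world
axes, origin at the grid centre, AC-PC plane at z = 0):

* **Regions** — axis-aligned ellipsoids (thalamus with a VLpv-like and a
  VPLp-like nucleus inside it, cerebellum with a dentate nucleus, superior
  cerebellar peduncle, red nucleus) and boxes (precentral, postcentral and
  supplementary-motor cortex), mirror-symmetric about the midline.  All
  coordinates are expressed in units of the grid half-extent, so the
  anatomy scales with the requested grid; the smallest legal grid is 32^3.
  Voxelisation uses 3^3-per-voxel supersampled majority occupancy, which
  keeps voxel counts close to the analytic volumes.  Deep way-point nuclei
  are painted last so that no warp can erode them against larger
  neighbours.
* **Bundles** — tubes of 4 mm radius around cubic-spline centerlines:
  thalamocortical bundles from the VLpv to the precentral and supplementary
  motor cortex, from the VPLp to the postcentral cortex, and a decussating
  cerebello-thalamic arc (contralateral dentate → contralateral SCP →
  midline → ipsilateral red nucleus → VLpv).  Each voxel within a tube
  carries the tangent of the nearest centerline sample as its mean fibre
  direction; where two bundles cross at more than 25 degrees the voxel
  stores both populations with equal volume fractions.  The centerlines are
  retained as exact oracle trajectories for tracker tests.
* **Inter-subject variability** — a smooth random warp, the sum of three
  low-frequency sinusoidal displacement fields with random wave vectors and
  phases, rescaled so its RMS magnitude over the grid equals
  `subject_displacement_mm` (default 1.5 mm, a plausible residual after
  non-linear spatial normalisation).  The warp displaces the analytic
  primitives (region centres, spline control points) before re-voxelisation
  rather than resampling voxel arrays: shapes are preserved, the analytic
  centerlines remain exact, and the expected centre-of-gravity shift of any
  region equals the configured RMS.  A warp that would push a region
  off-grid is halved until it fits (logged).
* **Inter-scanner variability** — per scanner, the Watson concentration is
  reduced by an additive `scanner_dispersion_delta` (defaults 0/20/40) and
  the mean directions are perturbed by a scanner-specific Gaussian field
  with SD `direction_jitter_per_delta * delta` radians (default 0.006).
  The perturbation field is drawn once per scanner on the full grid, so it
  is identical across subjects scanned on the same machine — a reproducible
  vendor bias, not noise.  The defaults were chosen so the scanner and
  subject effects have comparable impact on target overlap, mirroring the
  finding the phantom emulates.  The true mechanism of scanner differences
  in vivo is unknown; this model is one deliberate choice among many.
* **Seeding** — hierarchical: master seed → per-subject warp streams →
  per-scanner perturbation streams → per-run tracking streams.  The whole
  phantom set is a pure function of its configuration; adding a scanner
  does not change existing subjects.

What the phantom does **not** emulate: imaging artifacts (eddy currents,
susceptibility distortion, fat-suppression differences), registration
error, asymmetric anatomy, partial-volume fibre geometry beyond two
discrete populations, or the true biological covariance of anatomy.
Passing tests on the phantom therefore demonstrate the correctness and
statistical calibration of the *pipeline*, not the accuracy of tractography
on real data.

## Orientation model and DWI synthesis

Each valid voxel carries up to two mean unit directions with volume
fractions and a Watson (axial, antipodally symmetric) concentration kappa
(default 60, roughly a 7-degree mean deviation).  Sampling uses rejection
from a truncated-exponential envelope with ≥50% acceptance at any kappa;
`kappa = inf` returns the mean exactly, giving deterministic limit fields
for oracle tests.  The Watson model is a deliberate parametric stand-in for
a full Bayesian multi-fibre posterior: it preserves the tracker's
stochastic-orientation contract at a tiny fraction of the cost.

DWI synthesis is monoexponential (S = S0 exp(-b gᵀDg)) from prolate
per-population tensors (lambda_parallel 1.7e-3, lambda_perp 3e-4 mm²/s,
isotropic background ADC 8e-4), with a deterministic spherical-Fibonacci
gradient scheme (default 32 directions at b = 1000 s/mm²) and optional
multiplicative Gaussian intensity noise.  The tensor fit is log-linear
least squares; it is exact on noise-free data, which the round-trip tests
assert at 1e-6 relative error.  Fractional anisotropy uses the standard
eigenvalue formula with a single square root so the closed-form cases 0 and
1 are hit exactly.

## Tracking

Streamlines advance with a fixed step (default half the smallest voxel
dimension) using midpoint (RK2-style) refinement: a direction is drawn at
the current voxel, the orientation is re-evaluated at the half-step
position, and the streamline advances along the refined direction.  On
curved analytic fields this keeps trajectories within a fraction of one
step of the true centerline, where plain Euler stepping drifts outward by
~0.8 steps over a quarter turn.  Orientation lookup is nearest-neighbour in
voxel space — directions are never interpolated, which would average across
the antipodal ambiguity.

Rules, in the order applied after each step: mask exit (leaving the grid or
the valid orientation mask; a target entered on the same step still
counts), first-target credit (the sample is credited to the first target
region it enters, then terminated — no double counting across a
multi-target run), ordered way-point bookkeeping, and the loop rule
(terminate on re-entering any voxel this streamline already visited).  The
per-step turning limit is 80 degrees; the step cap is 2000.

In two-population voxels a *propagating* streamline follows the population
whose mean axis best aligns with its incoming direction; only the free draw
at seeding chooses proportionally to volume fraction.  Pure
fraction-proportional choice was tried first and discarded: at the
decussation, where the two cerebello-thalamic arcs cross, it re-flips the
population every step and terminates essentially all streamlines by
curvature or loop.  Alignment-following is what multi-fibre trackers do in
practice and leaves crossings transparent to through-going fibres.

Each seed voxel launches `samples_per_seed_voxel` streamlines (default
5000, the emulated protocol value; reduced sizes are used in tests and in
the acceptance script, see below) with uniform jitter inside the voxel.
The initial axial sign is random, so on a one-way bundle roughly half the
samples leave against the bundle and are lost — ordinary behaviour for a
unidirectional probabilistic tracker.  Counters are per seed voxel and per
target; the waytotal is the number of samples that reached any target, and
waytotal normalisation divides every counter by it.  Because percentile
thresholds are scale-free, targets built from raw counts and normalised
maps are voxel-identical (asserted over random maps).

Way-point filtering keeps a streamline iff it enters the way-point masks in
the stated order — gaps are allowed, entering a later way-point before an
earlier one disqualifies permanently — and then reaches the terminal
target.  The cerebello-thalamic recipe seeds the dentate contralateral to
the target thalamus with way-points [contralateral SCP, red nucleus dilated
by four 6-connected voxels].

## Targets, metrics and the threshold sweep

A connectivity-based target (CBT) is the voxel set at or above the
linear-interpolation ("type 7") quantile of the map's strictly positive
values, for integer percentiles 50..100.  The retention rule is `value >=
cutoff` with a 1e-12 relative slack so positive rescaling cannot flip
boundary voxels.  Overlap is the Dice coefficient 2|X∩Y|/(|X|+|Y|) on voxel
sets; distance is the Euclidean separation in mm of the intensity-weighted
centre of gravity of the thresholded map from the binary centroid of the
atlas target (the weighted choice for connectivity volumes is a documented
decision; a binary flag is available).  Degenerate thresholds are recorded
as missing, never dropped silently.

## Consensus threshold optimisation

Lower thresholds make targets more reproducible across subjects but less
anatomically specific; higher thresholds the reverse.  The optimum is the
percentile maximising the product of (a) the median pairwise inter-subject
Dice — different-subject, same-scanner pairs, pooled across scanners — and
(b) the median Dice against the atlas target, computed separately per
intent and hemisphere.  Ties break toward the lowest percentile (the more
inclusive, safer-to-review volume).  Both aggregations use medians
throughout.

## Reproducibility decomposition

At each intent's optimal percentile, all unordered pairs of
(subject, scanner) units are tagged inter-scanner (same subject, different
scanner), inter-subject (different subject, same scanner) or crossed (both
differ).  The report gives group means ± SD, a two-sided Welch t-test
p-value for the tagged-group difference, and the overall mean ± SD across
all pairs including crossed ones.  Pairwise Dice values sharing a unit are
not independent; the Welch default is nevertheless well calibrated in this
design (empirical type-I rate 0.035 at alpha 0.05 over 200 null
replicates, inside [0.01, 0.12]), and a permutation alternative that
permutes unit identities (10,000 seeded permutations) is available via
`test="permutation"`.  The calibration null is realised as a phantom with
all structural effects at zero, so units differ only by independent
tracking Monte-Carlo noise — the exchangeable case.  The power check uses a
scanner-dominant design (subject displacement 0.1 mm against dispersion
deltas (0, 15, 30) with direction jitter 0.012) and pools the pairwise
tables of the two hemispheres, which are independent realisations of the
scanner bias fields.

The cerebello-thalamic tract has no atlas target, so no consensus optimum
exists for it.  Its maps are first restricted to a 40 mm slab centred on
the AC-PC plane (20 mm ventral, 20 mm dorsal — the neurosurgical working
volume), then thresholded at the fixed 90th percentile of the restricted
non-zero values; the order slab-then-threshold is asserted by test, since
the reverse order changes the result whenever high connectivity values lie
outside the slab.  Units whose restricted map is empty are excluded and
logged.

## Numerical and degenerate-input choices

* Quantiles: numpy's linear interpolation on sorted positive values;
  all-zero maps are an error, never a silent empty target.
* Dice of two empty volumes is an error; `D = 1` iff the sets are equal.
* A zero waytotal yields an all-zero normalised map with a warning; double
  normalisation is an error.
* Welch's test on two constant, equal groups returns p = 1 (no evidence of
  a difference) instead of the 0/0 form.
* Voxel-count conservation under the subject warp holds to 10% only for
  structures well above voxel scale; for spheres 1-2 voxels in radius, the
  discrete count legitimately swings by ±40% under sub-voxel translation,
  which is voxelisation, not volume change.

## Problem sizes used in tests and the acceptance script

The package defaults keep the emulated protocol values (5000 samples per
seed voxel, 32 gradient directions, b = 1000).  The test-suite and the
acceptance script use reduced, fixed problem sizes chosen as a deliberate
scaling of the same design: the acceptance script runs the full 4-subject ×
3-scanner study on the default 48^3 grid at 100 samples per seed voxel; the
end-to-end determinism check uses a 32^3 grid with 2×2 units at 200
samples; the statistical power and calibration checks seed from the
motor-relay nucleus at 250 and 40 samples respectively.  Monte-Carlo noise
at these sizes is part of the reported numbers; all of it is controlled by
the single master seed.

## Known limitations

* The Watson single-concentration model cannot represent fanning or
  asymmetric dispersion, and the two-population cap hides three-way
  crossings.
* Alignment-based population choice makes branch selection at sub-threshold
  crossing angles deterministic given the incoming direction; branching
  then happens through dispersion and seeding randomness only.
* The phantom's mirror symmetry means hemispheric asymmetries of real
  anatomy are not modelled; left/right differences in outputs are pure
  sampling noise.
* Pairwise-Dice dependence is handled empirically (calibration checked),
  not by a variance-component model; an ICC-style mixed model is out of
  scope.
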