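# Methods

This note documents the models, conventions and numerical choices behind
`mclegz`, and what the synthetic phantom does and does not establish about
real data.

## Signal model and relaxometry

Under an inversion-recovery acquisition with a continuous (SSFP-style)
readout, voxel signal recovers as

    S(t) = A − B · exp(−t / T1*)

where `A` is the steady-state amplitude the voxel recovers toward, `B` the
inversion depth (`B = 2A` for a perfect inversion) and `T1*` the apparent
relaxation time under the readout. The fitter estimates all three
parameters per voxel rather than fixing `B = 2A`, because real inversions
are imperfect; the phantom's `B/A` ratio is configurable for the same
reason (default 2, ideal inversion).

Fitting is nonlinear least squares: a coarse log-spaced grid over `T1*`
(48 nodes in [10, 5000] ms) with an exact linear solve for `(A, B)` at each
node initializes a damped Gauss–Newton (Levenberg–Marquardt) refinement run
vectorized across voxels. Steps are accepted per voxel only when they
reduce the residual, so the refined fit never does worse than its starting
point. Convergence is a relative parameter change below 1e-8 (at most 200
iterations). A voxel is marked invalid when it fails to converge, ends on
the `T1*` bounds, or carries no recovery information (|B| below 1e-6 of
the signal scale — e.g. a constant signal, for which `T1*` is
unidentifiable). For magnitude data, polarity is restored by refitting
with the earliest j frames negated for every j and keeping the
lowest-residual fit per voxel.

Zero-spread degenerate inputs elsewhere follow the same spirit: the pooled
t-test treats a pooled SD at floating-point roundoff of the means
(≤ 1e-12 relative) as exactly zero, returning p = 1 for equal means.

### Frame selection

`select_frames` keeps the last k = 8 frames (largest TIs) by default —
the diastolic end of a cardiac-phase-resolved acquisition, where motion is
minimal; an explicit index override is available. The *pipeline* default
fits **all** frames of a simulated series instead: phantom frames are
co-registered by construction, and a design study showed the late-TI-only
window is severely ill-conditioned for the three-parameter exponential
(median T1* error ≈ 50% at 2% noise, versus ≈ 5–10% using the full
schedule). For real, moving data the diastolic subset remains the right
choice; for simulation it discards information for no benefit.

## Phantom

A short-axis stack (default 64×64×3 voxels at 1.5 mm in-plane, 8 mm
slices) containing:

* blood pool: radius < 20 mm from the LV centre;
* myocardium: annulus between 20 and 30 mm;
* infarct core: a 90° wedge from the endocardium to a transmural fraction
  (default 1.0) of the wall;
* gray-zone rim: myocardial voxels within 3 mm (in-plane Euclidean
  distance) of the core, clipped to the wall;
* two 4 mm papillary muscles 12 mm from the centre (one infarcted by
  default; both flags configurable).

Tissue signal table (arbitrary units / ms): blood (A = 120, T1* = 250),
core (100, 320), healthy (80, 600). These encode the post-gadolinium
ordering — blood and infarct recover fast while the nulled healthy wall
recovers slowest — and are conventions of the phantom, not measured
values. Gray-zone ground truth is a 50/50 linear mix of core and healthy
parameters (configurable), since the gray zone is defined operationally,
not biophysically.

The MCLE schedule is 20 TIs linearly spaced 150–950 ms, emulating 20
cardiac-phase-resolved images across one ~950 ms R-R interval; all tissue
null points fall before the late frames. The IR-FGRE image is a single
magnitude image at the healthy null (`T1*_healthy · ln 2 ≈ 416` ms, inside
the typical 200–300 ms window only for shorter healthy T1*; the null time
follows the phantom's tissue table). Noise is i.i.d. Gaussian per voxel
per frame (Rician effects are ignored; the magnitude option exists but the
default signed path feeds the fitter directly).

What the phantom does **not** emulate: cardiac/respiratory motion,
partial-volume point spread, coil shading, Rician noise floors, irregular
infarct shapes, and inter-subject anatomical variation. Passing the
phantom suites therefore establishes correctness of the *algorithms* under
the stated signal model, not clinical performance.

## FWHM segmentation

Candidate infarct: myocardial voxels with SI strictly above `Peak_remote`
(the only remote-derived cutoff the method uses). `Peak_infarct` is the
candidate maximum; core is `SI > 0.5·Peak_infarct` (strict), gray zone
`Peak_remote < SI ≤ 0.5·Peak_infarct`. The half-maximum boundary voxel is
assigned to the gray zone by default (`gz_upper_inclusive=False` gives the
strict reading, leaving it healthy). `SD_remote` is computed (sample SD,
ddof = 1) and reported but enters no threshold. The masks commute with a
pure positive rescaling of image plus statistics; an additive intensity
offset genuinely moves the half-maximum cut, so offset invariance is not
claimed. An empty candidate region returns empty masks with an explicit
flag rather than an error.

## MCLE segmentation

Features are per-voxel (T1*, A) pairs over the analysis mask (invalid fits
dropped, counts logged), z-scored per feature with the parameters stored
for exact inversion. Fuzzy C-means uses k = 3 clusters, fuzzifier m = 2,
squared Euclidean distance, membership tolerance 1e-5, at most 300
iterations, and 5 restarts seeded from a master seed; each restart draws
greedy k-means++ centroids (4 candidates per step) refined by a short hard
k-means pass before the fuzzy updates. Plain k-means++ systematically
placed two centroids inside the widely dispersed healthy cluster under
noise, leaving core and blood merged; the greedy variant (as used by
standard k-means implementations) removes this failure mode. A point
coinciding with a centroid receives membership 1 there (ties split
equally). The best-objective restart is kept; the objective trace is
recorded and is non-increasing by construction of the alternating updates.

Clusters are named from their de-standardized centroids: blood has the
highest steady-state amplitude; of the remaining two, infarct has the
shorter T1* (fast post-contrast recovery) and healthy the longer. Ties
break toward shorter T1* (blood) with a warning.

Within the myocardium, the **infarct membership** is banded — core above
0.75, gray zone in [0.25, 0.75] (inclusive bounds), healthy below — and a
voxel whose blood membership exceeds 0.5 is labeled blood regardless
(cavity partial-volume guard). Banding the infarct membership is one
reading of "25–75% probability belonging to infarct or healthy"; when
blood membership is negligible inside the wall the two readings coincide.

Despeckle automates the manual cleanup of noise-driven isolated voxels:
face-connected components of core ∪ gray zone smaller than 2 voxels whose
myocardial neighbours are all healthy are relabeled healthy. Components
touching other infarct tissue, or sitting at the blood/background border
with no healthy neighbour, are left alone ("within healthy myocardium"
read literally). No other spatial regularization is applied.

## Quantification

Masses are voxel count × voxel volume × 1.05 g/cm³ (standard myocardial
density convention). Heterogeneity percentages are normalized to LV
myocardial mass (the wall mask); gray zone counts toward total infarct and
toward LV mass, so core + GZ + healthy mass equals LV mass exactly by
construction. Papillary muscles are excluded from the wall for these
percentages and scored separately: a PM is infarcted when ≥ 50% of its
voxels (inclusive) are classified core or gray zone, or — on the intensity
path — when its mean SI reaches the FWHM core threshold
`0.5 · Peak_infarct`, operationalizing "enhancement similar to adjacent
infarct"; both thresholds are configurable, since no quantitative
definition exists. LV volumes use summation of disks (endocardial area ×
slice thickness per slice); ED/ES are the max/min-volume phases; LV mass
is the epi-minus-endo shell at ED times density.

## Cohort statistics

The two-sample comparison is the pooled-variance Student t-test
(two-sided):

    sp² = ((n1−1)s1² + (n2−1)s2²) / (n1+n2−2),
    t = (m1 − m2) / (sp·√(1/n1 + 1/n2)),   df = n1 + n2 − 2.

The summary-statistics route and the raw-values route agree to 1e-12 by
construction (the raw route computes the summaries first). Fisher's exact
test uses the probability-mass two-sided rule — the sum of hypergeometric
probabilities, at fixed margins, of all tables no more probable than the
observed one — which is the most common convention and the one scipy
implements; the tests verify it against explicit enumeration. Sample SDs
use ddof = 1 throughout (the `mean ± SD` convention of cohort tables).

p-values recomputed from printed one-decimal summaries inherit their input
rounding: a tolerance of ±0.005 (±0.01 for values near 0.2) is the honest
reproduction band, and one printed value (gray zone / LVM by the
multi-contrast method, printed 0.046) recomputes to ≈ 0.050 from the
rounded summaries — the unrounded data evidently sat just under the
significance line.

The cohort simulator draws continuous measures per group as Normal(mean,
sd) clipped at zero and PM scores categorically; category probabilities
(0.03, 0.27, 0.70) and (0.40, 0.20, 0.40) reproduce the per-group PM-score
mean ± SD of 1.67 ± 0.49 and 1.00 ± 0.89. Per-subject totals are
recomputed as core + gray zone so additivity holds exactly.

## Problem sizes and benchmarks

The test and acceptance workloads use the default 64×64×3 phantom
(≈ 3800 analyzable voxels), 20 noisy end-to-end replicates at noise
sd = 2% of the blood amplitude (2.4 a.u.), 1000-voxel relaxometry sweeps,
and exhaustive Fisher enumeration over all 2×2 tables with total ≤ 25
(23 751 tables). The noisy relaxometry benchmark uses 20 log-spaced TIs
from 50 to 4000 ms — a standard inversion-recovery T1-measurement
protocol spanning the full recovery of every simulated T1*; on sparse
8-point schedules confined to 100–800 ms the Cramér–Rao bound alone
exceeds the benchmark's accuracy, so the protocol choice is part of the
experiment design, fixed by that bound before measurement.

## Known limitations

* Per-volume, intensity-only clustering; no spatial features or
  regularization beyond despeckling.
* No motion correction or registration; frames are assumed co-registered.
* The remote ROI and all masks are inputs (phantom-generated here);
  nothing is auto-contoured.
* Gaussian noise only; magnitude/Rician effects are available but not the
  default and not modeled in the noise floor.
* The FWHM path's candidate-infarct definition (SI above the remote peak)
  is one defensible operationalization; others (e.g. SD-based cutoffs)
  would shift the gray-zone band.
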