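# Methods

This note records the models, numerical conventions and design choices
behind `doseval`, in the order data flows through the package.

## Coordinate and voxel conventions

All geometry lives on a shared regular lattice (`Grid3D`): axis order
(z, y, x), spacing in mm, origin at the *center* of voxel (0, 0, 0), patient
axes following DICOM LPS (+x left, +y posterior, +z superior).  Doses and
masks entering a comparison must be on the same lattice to within 1e-6 mm;
there is no implicit resampling — silently resampling clinical dose grids is
a classic source of irreproducible metrics, so a mismatch is an error.

Voxel membership is center-based everywhere: a voxel belongs to a structure
iff its center lies inside an odd number of the slice's polygons (even-odd
rule, matching RT Structure Set practice).  No partial-volume weighting is
applied, so volumes, DVHs and overlap metrics are exact set operations on
voxel sets and every metric is reproducible to the bit.

## Structures

*Mask → contours* uses marching squares (`skimage.measure.find_contours`) at
the 0.5 iso-level on each slice, padded so border structures close; outer
boundaries are oriented counter-clockwise, holes clockwise (nesting parity
decides which is which).  *Contours → mask* rasterizes by the even-odd rule
at voxel centers.  The pair is mutually inverse on solid structures without
single-voxel-thin features, which the test suite checks on random blobs.

*Outlier removal* keeps the largest 26-connected component (ties broken by
smallest lexicographic voxel index) and is idempotent.  *Contour smoothing*
is a circular moving average of polygon vertices (default window 3); the
algorithm used clinically for this step is generally not reported, so this
is a deliberate, simple, testable choice — window 1 is the identity, convex
polygons strictly lose perimeter, and circularly symmetric shapes keep
their centroid.

*Signed distance fields* are Euclidean distance transforms
(`scipy.ndimage.distance_transform_edt`, anisotropic sampling): an outside
voxel carries the distance to the nearest inside voxel center (and vice
versa, negated), so thresholding at 0 reproduces the mask exactly and
thresholding at +m equals isotropic expansion by m.

*CTV → PTV expansion* dilates with the exact anisotropic footprint: a voxel
joins the PTV iff some CTV voxel lies within the "egg" whose six half-axes
are the per-direction margins (posterior typically smaller, sparing the
rectum).  The footprint is evaluated at voxel-center offsets and applied by
FFT convolution; on a discrete lattice this is identical to thresholding a
per-axis-scaled distance field but handles the posterior/anterior asymmetry
without any special-casing.  Expansion is monotone in every margin
component and always contains the CTV.

## Geometric agreement

DSC is reported in percent.  Surface distances are measured between centers
of boundary voxels (mask voxels with a face neighbour outside; the grid
border counts as outside): both directed nearest-neighbour distance sets are
pooled, HD is their maximum, HD95 the 95th percentile (linear interpolation
between order statistics), ASD the mean.  Sub-voxel (mesh-based) surface
distances are out of scope; at 2 mm voxels this quantizes small distances,
which matters for the parameter-recovery experiment below.

## DVH engine

DVHs store the full sorted vector of in-structure voxel doses — no binning,
hence no bin-width parameter and exact queries.  VdGy uses a closed bound
(dose ≥ d).  Dx% is the (1 − x/100) quantile under the midpoint-rank
convention with linear interpolation: query position q·n + 0.5 in 1-based
rank space, clamped to [1, n].  Clinical planning systems differ in exactly
this convention; it is fixed and documented here because it changes answers
at small n.  Two consequences worth knowing: D95% of {60, 65, 70, 75} Gy is
60.0 Gy (the clamp), and the round trip V(D(x)) ≥ x holds only to within one
voxel's volume fraction (100/n %), because the interpolated quantile can sit
just above the order statistic that carries the coverage.  Relative-volume
denominators are used throughout (D95% means percent of structure volume).

## Plan-quality indices and criteria

HI = (D2% − D98%)/D50% with this engine's Dx convention; 0 for a perfectly
uniform target dose, and documented as lower-is-better.  CI =
(TV_RI/TV)·(TV_RI/V_RI) with the reference isodose at 95% of prescription
(configurable); the first factor is coverage, the second sparing, and
TV_RI² ≤ TV·V_RI keeps CI in [0, 1].  V_RI is counted over the whole dose
grid because no body contour is modelled — a documented limitation that
slightly depresses CI when dose spills near the grid border.

The constraint checker evaluates JSON rule lists (Dx%, VdGy, V at %PD,
Dmean, Dmax against </>/≤/≥ limits).  The shipped 3D-CRT table encodes the
standard pelvic objectives (CTV V(100%PD) ≥ 100%, PTV V(95%PD) > 95%,
bladder and rectum V50/V65 limits, femoral-head Dmean < 37 Gy and
Dmax < 55 Gy).  The rectum V65 threshold is encoded as < 25% but flagged in
its `note` field: the source material for that cell is ambiguous and the
value should be reviewed before clinical use.

## Gamma analysis

For each reference voxel at or above the low-dose cutoff (default 10% of
prescription, applied to the *reference* dose), the gamma index is the
minimum over displacements r, |r| ≤ 3·dta, of

    sqrt( (|r|/dta)² + ((De(x+r) − Dr(x)) / (tol·Dn))² )

with the evaluated dose trilinearly interpolated on a sub-voxel lattice of
pitch 0.1·dta (both the truncation radius and the pitch are configurable).
The normalization dose Dn is global and defaults to the prescription — the
same scale on which the cutoff is defined.  γ = 1 exactly counts as a pass.
Samples falling outside the evaluated grid are skipped, never extrapolated.

The search iterates displacements in order of increasing magnitude and
retires each voxel as soon as no remaining displacement can improve it.
Retirement combines the spatial term with banded dose bounds: local min/max
filters of the evaluated dose over boxes covering balls of radius 1, 2 and
3 × dta give, per voxel, a lower bound on the dose term anywhere in each
band.  This makes well-agreeing distributions (the clinical QA case) cheap
while leaving results bit-identical to the unpruned search — the test suite
compares against an exhaustive fine-lattice oracle and against the pure
numpy path (the inner loop is numba-compiled when numba is available).
Discretization of the search lattice itself bounds the gamma error by about
(pitch/2)·(max(|∇De|)/(tol·Dn) + 1/dta); at the default pitch this is well
under 0.05 for clinical-scale gradients.

## Statistics

Wilcoxon signed-rank (paired sets): zero differences are dropped
(Wilcoxon's original treatment), |differences| are midranked, and for
n ≤ 20 the exact two-sided p comes from the full null distribution of W+
over all 2ⁿ sign assignments, computed by a convolution over doubled
midranks (doubling makes tied midranks integral, so ties are handled
exactly); p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).  Beyond n = 20 the tie-
and continuity-corrected normal approximation is used
(`scipy.stats.wilcoxon`).  Mann-Whitney U (independent samples, used for
DSC comparisons between contour-set pairs) is exact for n+m ≤ 16 without
ties and otherwise tie-corrected asymptotic (`scipy.stats.mannwhitneyu`).
Both switchover thresholds are arguments.  No multiple-testing correction
is applied by default, matching a per-metric 0.05 threshold; a Holm
step-down option exists.

The comparison table reports, per structure × metric, mean ± SD for each
contour set, mean ± SD of per-case |EC−OC| and |AC−OC|, and Wilcoxon
p-values with significance flags.  When every per-case difference is zero
the test is undefined; the table carries p = NaN with an explicit
`p_*_defined = False` flag rather than a fabricated 1.0.

## Synthetic phantom

The phantom stands in for planning-CT anatomy: a prostate-sized CTV
ellipsoid (defaults 19 × 17 × 22 mm semi-axes, ≈ 30 cm³), a bladder
ellipsoid anterior-superior, a curved rectum tube posterior (8 mm radius),
and two 21 mm femoral-head spheres at ±62 mm lateral, on a 96 × 96 × 64
grid at 2 mm isotropic (kept at 2 mm so a full cohort runs comfortably on a
laptop).  Per-case anatomy jitters sizes by ±10% and positions by ±3 mm;
overlaps are resolved by priority (CTV > rectum > bladder > femoral heads)
so organs are always pairwise disjoint, and every organ must fit the grid
with a 2-voxel border.  Everything is deterministic given seeds
(`numpy.random.SeedSequence` spawning).

**Observer model.**  A simulated observer's contour is the sub-zero level
set of the original signed distance field plus a smooth zero-mean Gaussian
random field (white noise smoothed at a 10 mm correlation length) and an
optional rigid shift.  The field is normalized to mean 0 and SD = amplitude
over the structure's boundary shell, not the whole grid: the global
normalization would let the field's local mean act as a random systematic
shift and inflate the seed-to-seed spread of DSC several-fold beyond what
contouring variability shows.  Amplitude 0 with zero shift is the exact
identity; DSC decreases monotonically with amplitude, which is what makes
the model calibratable by bisection (`calibrate_amplitude`).

Shipped per-organ amplitudes were calibrated once, by bisection on the
cohort-mean DSC over jittered phantoms, to emulate reported agreement
levels: the expert pair at DSC ≈ 90.0 (CTV), 93.2 (bladder), 91.6 (rectum),
94.5 (femoral heads); the auto-contour model better than the second expert
for bladder and femoral heads, slightly better for CTV, and worse for the
rectum.  With these constants the auto-vs-expert ordering holds in ≳ 95% of
single-case replicates for the organs where it is imposed.

**What the emulation does and does not show.**  The perturbation is a
stationary smooth boundary displacement; real observer variability also has
anatomy-driven structure (systematic disagreement at the prostate apex and
base, bladder-filling differences), and real auto-segmentation errors can
be topological.  Passing the calibration tests shows the pipeline's
statistics behave correctly at realistic agreement levels — not that the
model reproduces clinical disagreement patterns.

**Parameter recovery.**  For a Gaussian displacement field the average
surface distance between original and perturbed structure is
E|ε| = amplitude·√(2/π), so amplitude ≈ ASD·√(π/2).  The estimator assumes
the displacement is resolved by the lattice: at the default 2 mm voxels
with ~2.5 mm amplitudes, center-to-center surface distances quantize and
bias ASD low by ~30–40%.  The recovery experiment therefore runs on a 1 mm
lattice with a 3 mm amplitude, where the estimator lands within ~10% (and
the acceptance check requires 20%).

**Dose surrogates.**  Not transport calculations — parametric fields with
realistic gradients so every downstream metric has something to measure.

- `box4` (3D-CRT-like, default 70 Gy): four orthogonal beams (opposed
  anterior/posterior, weight 0.3 each; opposed laterals, 0.2 each).  Each
  aperture is the PTV's beam's-eye-view projection dilated by 7 mm, edges
  blurred with a 4 mm Gaussian penumbra, attenuated exponentially with
  depth at 0.003/mm; opposed pairs flatten the depth dependence across the
  target.
- `imrt_like` (default 78 Gy): sigmoid of the PTV signed distance, shifted
  outward by an 11 mm coverage margin with a 3 mm falloff, plus a 10% dose
  bath.  The shift puts the whole PTV on the flat shoulder (coverage) while
  the falloff sets conformity; the default lands CI ≈ 0.83 and D2% ≈ 100.5%
  of prescription.  Dose at signed distance beyond coverage_margin +
  5·falloff stays within one percent of the bath level.

Both are renormalized so the mean PTV dose equals the prescription
(to < 0.1%), and construction fails loudly if the plan misses the target
coverage objective V(95%PD) > 95%.

**Cohorts.**  Each case: reference organs (OC), expert and auto
perturbations of every organ (EC, AC), per-case margins sampled uniformly
from 6–10 mm (posterior 5–6 mm), one PTV per set from its own CTV, one plan
per set normalized to its own PTV — three plans per case, as in a
contour-set planning study.  A `degenerate=True` cohort (EC = AC = OC) is
the null pipeline check: all DSC 100, all Δ columns zero, gamma pass 100%.

## Pipeline conventions

Each plan's DVH panel is evaluated on its own contour set's structures —
the planning view: the AC row is the plan a clinic would deliver if it
trusted the auto contours.  Dose-distribution agreement is measured
separately as the 3%/3 mm gamma of the AC plan's dose against the OC plan's
dose.  Cohort statistics use Wilcoxon for the paired dosimetric metrics and
Mann-Whitney for DSC comparisons between contour-set pairs.  Incomplete
cases are skipped with a logged reason; a cohort with no complete case is
an error.  Outputs are plain CSV/JSON and re-running on the same inputs is
byte-identical.

## Problem sizes used in the shipped validation

The test suite validates at the scale the package is meant to run: DVH
oracle equivalence on 100 random ≤ 10³-voxel masks; gamma oracle
equivalence on twenty 20³ field pairs (engine and exhaustive oracle on a
matched 0.25 mm search lattice, plus a default-pitch consistency bound);
10⁴ null simulations at n = 20 for the type-I error of both tests;
50-phantom observer-calibration and 50-seed parameter-recovery studies; and
a 20-case end-to-end cohort.

## Known limitations

- Center-in-voxel semantics: metrics are exact for the voxelization, not
  for the underlying continuous anatomy; 2 mm voxels quantize surface
  distances (see parameter recovery).
- V_RI uses the whole grid as body surrogate (no external contour).
- Dose surrogates have no scatter, heterogeneity or MLC structure; gamma
  pass rates between surrogate plans are optimistic relative to clinical
  TPS recalculations.
- The DICOM writers emit minimal (though standard-conformant) datasets
  intended for round-tripping and testing, not for import into clinical
  systems.
- Grids must match exactly; resampling is deliberately out of scope.
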