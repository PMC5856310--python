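# Methods

## Scope and data model

All metrics are computed on a single rectilinear lattice: a dose grid in
Gy with per-axis spacing in mm, plus boolean structure masks aligned
voxel-for-voxel.  A voxel belongs to a structure iff its center is
inside the contour/mask; there is no partial-volume weighting.  Voxel
indices are 0-based and the physical position of voxel (i, j, k) is
`origin + index · spacing` with axis order (z, y, x).  DICOM RT Dose
grids that do not share the structure lattice are trilinearly resampled
onto it at load time (logged).  Units are fixed throughout: Gy, mm, cm³.

## DVH computation and point queries

The cumulative DVH is sampled at bin edges 0, w, 2w, … (default
w = 0.01 Gy); the value at each edge is the exact count of masked voxels
with dose ≥ edge, so the curve is exact at the edges, and every query
(D_q%, V_D) interpolates linearly between them.  The 0.01 Gy default
gives sub-percent dose resolution at SRS dose levels while keeping
curves small.  Consequences worth knowing:

- For a perfectly uniform dose the DVH is a cliff one bin wide, so D2%
  and D98% straddle it and HI vanishes only to within
  `bin_width / prescription` (10⁻⁴ at default settings).
- Halving the bin width moves any D_q% by less than the original bin
  width (tested).
- Structures with fewer than 50 voxels are flagged `low_resolution`:
  quantiles are still interpolated but resolve volume steps coarser
  than 2%.
- Dose-to-1cm³ falls back to the maximum dose (flagged) for structures
  smaller than 1 cm³, e.g. lenses on a 2 mm grid.

The target dose spread (`SDev`) is the population standard deviation of
the masked voxel doses as a percentage of their mean (a coefficient of
variation ×100).  Normalizing by the mean rather than the prescription
or maximum keeps the quantity scale-free across prescriptions; this is
a deliberate choice where conventions differ.

## Pooling heterogeneous prescriptions

Pooled-target metrics are reported over the union of all targets.  When
lesions carry different prescriptions (the general case here: 10–24 Gy
per lesion), the pooled DVH is computed on *relative* dose: every voxel
is divided by the prescription of its nearest lesion (Euclidean
distance to the lesion surface, zero inside), and the pooled
prescription level is 100%.  With one common prescription this reduces
to a plain division, so both conventions coincide.  The prescription
isodose volume for the Paddick indices is the whole-grid volume with
relative dose ≥ 100% and the half-prescription volume uses ≥ 50%, both
from voxel counts under the center rule.

## Plan normalization

Plans are globally rescaled so that `V_prescription = 95%` on the
pooled target.  The scale is found by iterating
`s ← s · prescription / D_95%` and accepting when the measured coverage
is within 0.05 percentage points (tighter than the 0.1-point contract);
if that iteration cycles between two binnings, a bisection on the scale
refines further.  Under the binned-DVH measurement convention the
achievable coverage values are quantized at roughly one voxel
(100/n %), so for very small pooled targets the best achievable
coverage may sit a few hundredths of a point off 95; the closest
achievable scale is returned, flagged `converged=False` when it misses
the 0.05-point tolerance.  True dose plateaus exactly at the
prescription level (e.g. a perfectly uniform plan, or a noiseless
lattice-quantized field) are detected by comparing the interpolated
coverage against the exact voxel-count coverage and are likewise
returned flagged rather than "converged" inside an interpolation cliff.
Normalization is idempotent to < 0.01% and leaves PCI/GI invariant when
the prescription is rescaled identically.

## The RPI

The score follows the printed double-product form: for k targets and n
OARs, the k×n bracketed factors `(1 − Wᵢ·Aᵢ) · Aⱼ · (1 − SDevⱼ/100·Wⱼ)`
are multiplied and the (k+n)-th root is taken.  Note the target factor
is repeated once per OAR; the literature is ambiguous on whether one
factor per *structure* was intended, so a `variant="per_structure"`
mode (plain geometric mean of k+n per-structure factors) is provided
for sensitivity analysis.  With n = 0 the k target factors under a k-th
root are used as the natural limit.  Default weights are 1.0 for every
structure (configurable per structure through a JSON config).

`A` is the trapezoidal area under the cumulative relative-volume DVH
from 0 to the structure's maximum dose across all compared plans,
normalized by 100·D_max; refinement of the bin width moves the RPI by
less than 10⁻³.  Three exact special cases keep the published boundary
behaviour exact rather than approximate: an unirradiated structure has
A = 0 (its DVH is a zero-width step), a structure uniformly at D_max
has A = 1, and a structure unirradiated in *every* compared plan
(D_max = 0) contributes A = 0.  The score is aggregated in log space
and is exactly 0 whenever any factor is 0.

When several plans of one patient are compared, `cross_plan_dmax`
shares each structure's maximum dose across the plans so all plans are
scored on a common dose axis; a structure present in a single plan
falls back to its own maximum with a warning.

## Synthetic cohorts and technique profiles

The simulator emulates the study conditions of a 15-patient
multi-metastasis planning cohort.  Each patient is an ellipsoidal brain
(semi-axes 60 × 80 × 65 mm, ≈ 1.3 l) with a fixed OAR template
(brainstem cylinder, chiasm box, paired optic-nerve cylinders, eyes and
lenses as spheres) at anatomically plausible offsets; keeping the OARs
fixed across patients keeps OAR metrics comparable within the cohort.
Lesion counts for the default 15-patient cohort are 11×3 and one
patient each with 4, 5, 6 and 8 (other cohort sizes draw from those
frequencies); lesion centers are rejection-sampled inside the brain
with a configurable minimum surface separation (default 10 mm, ≥ 5 mm
supported to exercise dose bridging).  Radii are uniform in 5–12.5 mm
and prescriptions decrease linearly with radius from 24 Gy (5 mm) to
15 Gy (12.5 mm) with ±1.5 Gy jitter, clipped to 10–24 Gy in 0.5 Gy
steps — echoing size-adaptive SRS prescribing.

A delivery technique is represented purely by dose shape:

| parameter | meaning | HA-like | VMAT-like | CK-like |
|---|---|---|---|---|
| `falloff_length` (mm) | exponential gradient scale outside lesions | 3.5 | 6.0 | 4.5 |
| `bath_level` (× mean Rx) | diffuse low-dose bath in the brain | 0.03 | 0.08 | 0.02 |
| `intra_target_heterogeneity` | fractional radial dose boost inside lesions | 0.20 | 0.05 | 0.15 |
| `bridging_gain` | amplification of overlapping kernel tails | 0.15 | 0.4 | 0.1 |
| `noise_sd` | multiplicative log-normal noise | 0.02 | 0.02 | 0.02 |

Each lesion contributes a kernel at its prescription with a parabolic
heterogeneity ripple inside the sphere and `exp(−(r−R)/λ)` outside;
kernels combine as `max + bridging_gain · (sum − max)` so an isolated
lesion peaks at its prescription while nearby lesions can bridge (pure
summation would overdose close pairs).  Tails are truncated at 12
falloff lengths past the surface (relative dose < 10⁻⁵).  The bath adds
`bath_level · mean(prescriptions)` inside the brain, noise multiplies
the field, and the plan is normalized to V100% = 95%.  Randomness is
driven by a single integer master seed with per-patient and
per-technique streams derived deterministically.

The profile values were fixed once so the emergent contrasts mirror the
qualitative clinical picture the simulator stands in for: the
single-isocenter non-coplanar profile has the steepest falloff (lowest
GI, smallest brain V4Gy) but the least homogeneous targets; the
conventional-arc profile the shallowest falloff and largest bath but
the most homogeneous targets; the robotic profile the smallest bath
(best distant-OAR sparing) with intermediate falloff and high target
heterogeneity.  These are dose-shape caricatures: the simulator does
not model beam transport, MLC sequences, arc geometry, collisions or
delivery time, and its absolute GI values (≈ 2–4 at these falloff
scales) sit below typical clinical multi-met values — passing tests
demonstrate the *metrics and comparison machinery*, and the direction
of technique contrasts, not clinical dosimetry.

## Cohort comparison

Each metric is compared across techniques with a Kruskal–Wallis test
(rank-based H with tie correction, chi-square approximation,
α = 0.05).  Completely tied groups carry no rank information and return
H = 0, p = 1.  When the omnibus test is significant with more than two
groups, pairwise two-group tests are run post hoc, uncorrected by
default (matching common practice in planning studies) with an optional
Holm correction.

One statistical caveat is documented deliberately: the comparison
design is *paired* — the same patients are rendered for every technique
— while Kruskal–Wallis assumes independent samples.  Under the null the
test is therefore conservative (measured rejection rate ≈ 0.01 at
α = 0.05 when patient geometry dominates noise).  The type-I
calibration test consequently draws independent patient groups per
replicate, where the measured rate matches the exact small-sample
chi-square rate (≈ 0.045 for three groups of eight).

## Problem sizes used by the test suite

Chosen as the package's own desk-scale defaults: unit tests run on
small analytic grids and a fixed three-lesion patient at 2 mm spacing;
the normalization and directional acceptance checks use the default
15-patient cohort at 2 mm; oracle-equivalence checks use 100 random
16³ grids; the type-I calibration uses 300 replicates × 3 independent
8-patient groups with three pooled metrics (900 tests); RPI properties
use 1000 random term sets.  A 1 mm grid is available via
`grid_spacing=1.0` for higher-fidelity runs.

## Known limitations

- The simulator's OAR doses are driven only by kernel tails and the
  bath; there are no beam-specific entrance/exit dose patterns.
- RT Structure Set rasterization supports closed planar contours with
  OR-composition per slice (no hole/XOR semantics) and axial identity
  orientation only; RT Dose writing quantizes at 10⁻⁴ Gy.
- The RPI weight vector is not published for the emulated study; the
  default (all 1.0) reproduces the printed boundary cases, and the
  score is known to be sensitive to this choice.
- Per-lesion (rather than pooled) conformity reporting and biologically
  effective dose conversion are out of scope.
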