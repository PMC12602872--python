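# Methods

## Coordinate standardization and sampling

A centerline arrives as ordered 3D points (mm) in an arbitrary scanner
frame. Each analysis plane has a standard frame: the horizontal (axial)
frame's abscissa is lateral distance from the sternal origin at the
fourth-rib insertion with the axial slice level fixed; the vertical
(parasagittal) frame's abscissa is inferior distance from the superior
manubrium with the parasagittal offset (one quarter of the thorax width)
fixed. Standardization translates the supplied anatomical origin to zero,
orients the abscissa to increase along the traced curve (sign-flipping
mirrored traces), re-sorts by abscissa and averages exact duplicates. The
fixed axis must be constant to within 1.5 mm — half of the 3-mm axial slice
thickness; larger spread indicates the points do not lie in one analysis
plane and is an error, not a warning.

Anterior projection is sampled at 10-mm intervals over 0–100 mm
(horizontal) or 0–120 mm (vertical), endpoints inclusive, by linear
interpolation between bracketing points; input points lying exactly on a
grid coordinate are used bit-for-bit. Linear interpolation is deliberate:
no smoothing is applied before the pointwise statistics (smoothing enters
only later through the polynomial fit), and its error is bounded by
h²·max|y″|/8 — under 0.1 mm for the 2-mm synthetic centerline spacing and
realistic curvatures. The origin and quarter-width offset are inputs;
detecting landmarks from images is out of scope, as is any voxel
processing.

## Pointwise comparison and omnibus test

At each grid point the sides are compared with an unpaired t statistic
using the unpooled standard error and df = n_L + n_R − 2, two-sided
p-values throughout (α = 0.05). The per-point chi-square value is the
square of the standard-normal quantile matching the two-sided p — a
p-matched conversion, computed in log space so |t| of several hundred still
yields a finite value. This conversion, not the naive t², reproduces the
reference pointwise chi-square columns ((t = 4.01, df = 98) → 14.80 where
t² = 16.08); the two agree only as df → ∞.

The omnibus statistic Q sums the per-point chi-squares. Grid points where
both sample SDs are zero (anchored origins) are excluded — the statistic is
undefined there and an anchored point carries no evidence; with no included
points Q = 0 with p = 1. Degrees of freedom follow the reference convention
(k − 1 for k included points) by default, with the theoretical k available
by flag. Under the theoretical convention and *independent* grid points,
Q is exactly χ²_k under the null (the conversion makes each term exactly
χ²₁). When subject-level deformations are smooth — the generator's default,
and surely true of real anatomy — neighboring grid points are positively
correlated, Q has inflated variance, and the omnibus test is
anticonservative (empirically ~15% type-I at the 5% level under the default
30-mm correlation length). This is a property of the method itself, not of
the implementation; the calibration checks therefore use pointwise-
independent noise, which is the regime the reference distribution assumes.
No multiple-testing correction is applied across grid points, and testing
is unpaired, matching the reference analysis (df = 98).

## Polynomial modeling and areas

Mean and per-subject curves are fitted by linear least squares over the
through-origin basis {s, …, s^d}: the standardized curves pass through the
anatomical origin by construction and the reference mean-curve polynomials
carry no constant term. Candidate degrees d = 1…5 (capped at 5 to limit
noise) are compared by unbiased residual variance RSS/(m − d); a higher
degree is adopted only if it improves on the incumbent by more than a
10⁻⁷ fraction of the mean squared signal, so ties on exact data resolve to
the lower degree deterministically. Vandermonde conditioning over spans of
100–120 mm with d ≤ 5 is benign in double precision (exact polynomials are
recovered to ~10⁻⁹ relative).

The signed area is the definite integral of the coefficient difference via
the exact antiderivative — no quadrature. Per-subject areas default to the
same fit-then-integrate procedure to mirror the mean-curve treatment; a
trapezoidal alternative on the pointwise differences is provided (the two
agree to a few mm² on smooth curves). Positive area means the left side
projects more anteriorly.

The vertical left curve does not pass through zero at its origin (the mean
offset there is the largest pointwise difference), so the through-origin
constraint induces a small systematic residual at s = 0 for that side; the
fitted-area consequence is below the sampling noise of the cohort sizes
used here. The printed vertical reference polynomials are numerically
inconsistent with the vertical grid means (their frame or sign is unclear)
and are stored for reference only, never used as ground truth.

## Volumes and distribution summaries

Plane volumes scale each mean-curve area by the orthogonal chest dimension
— horizontal area × 100 mm (grid width), vertical area × 120 mm (grid
height) — divided by 1000 to cc; this pairing reproduces the reference
volume chain 143 mm² → 14.3 cc and 202 mm² → 24.2 cc, and their mean,
19.3 cc (report rounding is decimal half-up, so 19.25 → 19.3). The opposite
pairing (each area times the *other* plane's dimension) can be configured.
These are planar-integration estimates and deliberately crude; true 3D
volumetry is out of scope.

Distribution summaries use the bias-corrected Fisher–Pearson skewness
(plain g₁ by flag), the D'Agostino skewness z-test, and the
D'Agostino–Pearson K² omnibus (z_skew² + z_kurt² against χ²₂). The
normal-approximation transforms behind these tests are unreliable in tiny
samples, so they require n ≥ 8; the target cohort size of 50 is far above.
Reports round volumes to 0.1 cc, areas to 1 mm² and statistics to two
decimals while retaining full precision internally.

## Synthetic cohort generator

The generator emulates the reference study conditions: 50 subjects, both
planes, grid means and SDs taken from monotone piecewise-cubic (PCHIP)
interpolants through the reference tables' right-side means, left-minus-
right offsets, and per-side SDs. Subject-level deformations are zero-mean
Gaussian with the tabulated pointwise SDs and squared-exponential
correlation along the grid. The correlation length (default 30 mm) is a
rib-scale smoothness choice the tables cannot constrain: some smoothness is
necessary for realistic centerlines and for the polynomial stage to behave
as it does on anatomy. Left and right deformations are independent by
default — the unpaired df = 98 of the reference analysis implies sides were
treated as independent samples — with a within-subject correlation knob for
sensitivity work. The horizontal origin is anchored (SD 0) on both sides,
which is what makes the omnibus df come out at the reference value of 9;
the tabulated nonzero right-side SD at that origin is inconsistent with an
anchored origin and is treated as a table artifact.

Each subject is emitted both as exact grid curves (ground truth) and as
dense centerlines at 2-mm spacing (PCHIP through the grid nodes, so
re-sampling recovers the truth exactly) in a randomly translated scanner
frame, with the fixed axis quantized to the 3-mm slice thickness and the
vertical plane placed at the quantized quarter of a per-subject thorax
width (normal, mean 234 mm, SD 17 mm, spanning the reference range).
Identical seeds give bit-identical cohorts.

What the generator does *not* emulate: segmentation error, within-slice
partial-volume effects, non-Gaussian anatomical variation, and any true
left–right coupling of real thoraces. Passing tests demonstrate the
pipeline's statistical behavior under the tabulated first- and second-
moment structure, not under real segmentation noise.

A note on sampling noise: with the tabulated SDs and smooth deformations, a
single 50-subject cohort estimates the mean-curve area with a standard
deviation near 100 mm², so individual simulated cohorts can even produce
negative horizontal mean areas despite the everywhere-positive generating
offset. Cohort-level claims are therefore checked as sampling-distribution
properties over replicates (power ≈ 81% for the horizontal omnibus at
n = 50), not on single draws.

## Verification problem sizes

Stochastic checks use sizes chosen by power analysis so that each bound
sits ≥ 4σ from its expectation: offset-field unbiasedness to 0.1 mm uses
500,000 subjects (the noisiest grid point has SE = √((sd_L²+sd_R²)/n) ≈
0.023 mm there); type-I calibration uses 1000 replicates (binomial SE
0.7 pp against a ±3 pp band); power uses 200 replicates at the study's
n = 50. Deterministic checks (chi-square conversion, omnibus sums, areas,
volume chain) run at the reference tables' own sizes.

## Known limitations

- The omnibus χ² reference distribution ignores between-point correlation
  (see above); a correlation-aware null would need the full covariance.
- The printed SE column of the reference tables is not reproducible from
  the printed SDs under any standard two-sample formula (likely computed on
  unrounded data); identities are therefore validated on printed
  (diff, SE) pairs rather than reconstructed from SDs.
- The reference vertical footer sums 12 of its 13 rows; this package's
  comparison includes every defined point, so its vertical omnibus df
  differs by one from the printed footer.
- Areas and volumes inherit the through-origin constraint and polynomial
  truncation; they are summary measures of planar sections, not volumetry.
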