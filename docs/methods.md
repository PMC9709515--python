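# Methods

## Model

A performance landscape is treated as a Monge patch: the graph
`S = {(x, y, f(x, y))}` of a height function over the rectangle
`Ω = [0, x*] × [0, y*]` of nutrient intakes, where `x*` and `y*` are the
maximum observed intakes.  The height is the quadratic polynomial

    f(x, y) = a x² + b y² + c x + d y + e xy + intercept,

fitted to the per-animal intake/trait records by ordinary least squares.
The quadratic family is the working assumption, not a claim about nature:
`compare_models` exists precisely to check, per dataset, that the quadratic
LM predicts held-out data about as well as the flexible smoothers (additive
spline GAM, thin-plate spline) that GF studies otherwise use.  When it
does, the closed-form coefficients make every downstream quantity cheap
and exact.

The regression includes an intercept even though the canonical polynomial
has none: trait data are not anchored at the origin, and the intercept
shifts height only — it cancels from every gradient, so curvature and
surface area are unaffected.

### Curvature

With `W = √(1 + f_x² + f_y²)`, the fundamental forms of a Monge patch are
`E = 1 + f_x²`, `F = f_x f_y`, `G = 1 + f_y²` and `L = f_xx/W`,
`M = f_xy/W`, `N = f_yy/W` (the second-form entries are the dot products
of the second-partial vectors `(0, 0, f_··)` with the unit normal; for a
Monge patch that reduces to division by `W`).  Then

    K = (LN − M²)/(EG − F²),    H = (GL − 2FM + EN)/(2(EG − F²)).

`EG − F² = 1 + f_x² + f_y² ≥ 1`, so the denominators never degenerate.
Principal curvatures are recovered as the roots of `κ² − 2Hκ + K = 0`
(the eigenvalues of the shape operator `I⁻¹II`); the discriminant
`H² − K ≥ 0` analytically and is clamped at 0 against roundoff.

**Normal orientation.**  The unit normal is the normalized cross product
of the tangent vectors `(1, 0, f_x) × (0, 1, f_y)` in that order — the
upward normal `(−f_x, −f_y, 1)/W`.  Under this orientation `H < 0` where
the landscape bends upwards (e.g. the first quadrant of `z = xy`) and
`H > 0` where it bends downwards.  Flipping the orientation would negate
`H` everywhere and leave `K` unchanged; the package fixes the upward
convention and documents it rather than exposing a switch.

**Flat classification tolerance.**  A point is classified flat when
`|K| ≤ tol`, convex when `K > tol`, hyperbolic when `K < −tol`.  The
default `tol = 1e-8` (dimensionless on min–max standardized domains) is
deliberately tight — it distinguishes exact zeros (planes, cylinders) from
numerically tiny curvature; users analysing noisy fits should widen it to
the scale of their coefficient uncertainty.  It is a parameter everywhere
it appears.

### Surface area

`A_S = ∬_Ω √(1 + f_x² + f_y²) dx dy`, by adaptive quadrature
(`scipy.integrate.dblquad`, absolute tolerance 1e-8 by default; failure to
converge raises an error carrying the estimate and bound rather than
returning silently).  The ratio against the flat reference is
`A = A_S / (x*·y*)`, since a flat landscape's area is the rectangle's.
The integrand is ≥ 1 pointwise, so `A ≥ 1` always, with equality iff the
gradient vanishes almost everywhere; the trait axis is kept on its
original scale here, so `A` measures deviation from flatness in the
trait's own units.  A Simpson-rule fallback (`surface_area_grid`) handles
landscapes that exist only as a grid of heights, with gradients by central
finite differences.

### Hausdorff comparison

Landscapes are compared as finite 3-D point sets on a *shared* grid
template (same domain, same resolution — enforced, with re-gridding
required otherwise).  Before distancing, the nutrient axes are min–max
standardized to `[0, 1]²` so neither axis dominates, and each trait axis
is divided by its mean (mean-standardization), which makes the distance
invariant to uniform rescaling of a trait's units.  The flat reference
height (1 by convention) is therefore arbitrary twice over: it has zero
curvature and unit area ratio regardless, and it standardizes to the same
constant-1 sheet whatever its value.

The directed distance uses `scipy.spatial.distance.directed_hausdorff`
(an exact early-break implementation); the test suite checks it against a
from-scratch double loop, exactly, up to 500-point sets.

**Bootstrap.**  95% CIs are percentile intervals over `n_boot = 1000`
resamples (default).  The resampling unit is the grid node: the same node
indices, drawn with replacement, are applied to both landscapes, which
preserves the paired, shared-domain structure.  Node resampling is a
design choice — resampling raw animals and refitting would propagate
regression uncertainty instead of grid-sampling uncertainty, and is
deliberately out of scope.  Reports carry both the full-grid point
estimate and the bootstrap mean; they need not coincide (resampled
distances can exceed or fall below the full-set value, since dropping
points from *both* sets moves the two directed suprema in opposite
directions).

## Model-comparison protocol

One 60/40 train/test split, uniform without stratification, seeded.  For
each of `n_resamples = 200` (default; the count is configurable) bootstrap
resamples of the training portion, three models are fitted — the quadratic
LM; an additive GAM `z ~ s(x) + s(y)` (statsmodels `GLMGam`, B-spline
bases, df 6 and degree 3 per axis, fixed penalty `alpha = 1`); and a
thin-plate spline (`RBFInterpolator`, smoothing ridge 1e-3 so duplicated
bootstrap rows keep the system nonsingular) — and their RMSE recorded on
the fitting resample and the held-out test set.  GAM knots are pinned to
the full data range so resample-fitted models can predict over the whole
domain.  RMSE is the root of the *mean* squared residual; comparisons
between models at fixed n are unchanged by the mean-vs-sum convention.
Back-end versions are recorded in the result metadata.

## Synthetic data

`GFDesign`/`simulate_gf_experiment` emulate the structure of a real GF
experiment: diets on nutritional rails (fixed P:C ratios) at several
dilutions, replicate animals per diet.  Defaults: rails at P:C = 1:8,
1:4, 1:2, 1:1, 2:1; dilutions at total intakes 0.25, 0.5, 0.75, 1.0 (in
standardized intake units); 10 replicates per diet (200 records); trait
noise SD 0.1; multiplicative log-normal intake jitter with log-SD 0.1.
The rail range and 4-step dilution series mirror the classic fly
lifespan/fecundity designs; the jitter model is an invention (real intakes
scatter multiplicatively around the diet's composition because animals
eat different amounts, not different foods).

What the simulator does *not* emulate: trait-dependent noise
(heteroscedasticity), non-quadratic true surfaces, censoring or death
before measurement, correlated traits within animals, and compensatory
feeding along rails.  Passing tests on simulated data therefore establish
that the pipeline recovers what it assumes — a quadratic surface plus
i.i.d. noise on a rail design — not that real landscapes are quadratic;
that question is what `compare_models` asks of each real dataset.

## Canonical validation surfaces

The flat landscape `(x, y, 1)` and saddle `(x, y, xy)` have closed-form
geometry (flat: `K = H = 0` everywhere, area ratio exactly 1; saddle at
the origin: `K = −1`, `H = 0`, principal curvatures `(1, −1)`, and
`H = −xy/(1 + x² + y²)^{3/2}` giving the quadrant sign pattern).  Sphere
and cylinder patches (`K = 1/r²`; `K = 0` with `H = −1/(2r)` at the crest)
validate the intrinsic/extrinsic distinction: the cylinder is an isometric
bend of the plane, indistinguishable by `K`, distinguished by `H`.

The saddle's surface-area ratio over the unit square is
`∬ √(1 + x² + y²) dx dy ≈ 1.28079`, cross-checked in the tests against a
from-scratch midpoint Riemann sum with 4×10⁶ cells.  No closed domain
assignment makes this ratio ≈ 4; the package treats the unit square as
the canonical benchmark domain and always reports the domain alongside
any ratio, since the ratio is domain-dependent (a wider domain with the
same coefficients has steeper gradients and a larger ratio).

## Numerical choices and edge cases

- Grids are closed (`[0, max]` inclusive), square, row-major; default
  101×101.  Area and Hausdorff outputs always record the resolution and
  domain used.
- Min–max standardization refuses constant vectors; mean-standardization
  refuses zero-mean vectors (both raise `DegenerateScaleError`).
- Rank-deficient quadratic designs raise `SingularDesignError` naming the
  collinear columns (QR with column pivoting).
- All stochastic steps (split, bootstrap resampling, simulation) take an
  explicit seed and are bitwise reproducible; the pipeline writes a
  manifest with seed, resolution, tolerances and package versions.
- Monte-Carlo recovery tests use Bonferroni-calibrated bands (five
  coefficients at a 5% joint level, 2.6 s.e. each) so the check has the
  advertised false-alarm rate.

## Problem sizes

Default analyses run at 101×101 grids with 1000 bootstrap replicates.
The test suite exercises the same code paths at 9–21 node grids, 10–200
bootstrap replicates and 50-replicate Monte-Carlo loops — sizes chosen so
the full suite completes in a few seconds while still resolving every
property it asserts (the curvature and area checks are resolution-robust;
only bootstrap CI width depends on the replicate count, and the tests
assert ordering and determinism, not CI endpoints).

## Limitations

- Two nutrient axes only; the differential geometry is specific to
  surfaces in 3-space, and no formulas are provided for higher-dimensional
  landscapes.
- Curvature and area are computed on the *fitted* quadratic; they inherit
  its misspecification.  Fit quality should be checked with
  `compare_models` before interpreting geometry.
- The Hausdorff bootstrap quantifies grid-resampling variability, not
  regression uncertainty in the fitted surfaces.
- No geodesics, curvature flows, or analytic antiderivatives (the area
  integral for a general quadratic is elliptic; numeric only).
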