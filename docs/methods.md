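# Methods

## The model

Adventitious GM presence in a conventional maize field is dominated by
pollen inflow across its borders. Two opposing quantities set the scale:
the external pollen that can enter is proportional to the perimeter `p`,
while the competing local pollen cloud is proportional to the area `A`.
Their ratio, the **Self-Protection Index**

    I = A / p        [m]

summarizes a field's resistance to cross-fertilization. The model's core
assumption is that two fields with the same `I` under equivalent external
pressure carry the same overall %GM, so every field can be mapped to an
*equivalent square* of side `a = 4I` (for a square of side `a`,
`A/p = a/4`).

Within the square, each border acts as a line source whose influence
decays with distance `d` as the equilateral hyperbola `1/(d + 1)` — the
empirical within-field decay of maize cross-pollination. Superposing the
four sides gives the density (percent of cross-fertilized kernels at a
point):

    rho(x, y) = K [ 1/(x+1) + 1/(y+1) + 1/(a-x+1) + 1/(a-y+1) ],
    0 <= x, y <= a

with one proportionality constant `K` (not itself a border mean). The
model is a model of *means*: it predicts averages over sets of points
equidistant from the border, never individual spots (those are dominated
by cob-level noise and the unknown donor configuration). Everything of
interest is an integral of `rho` with a closed form:

- mean along the perimeter at depth `d` (the contour is the concentric
  square of side `a − 2d`):

      Kbar(d) = K [ 2 ln((a−d+1)/(d+1)) + (a−2d)(1/(d+1) + 1/(a−d+1)) ]
                / (a − 2d)

  continuous at the degenerate centre `d = a/2`, where it equals the
  centre density `4K/(a/2 + 1)`;

- mean over the concentric region between depths `d1 < d2`:

      R(d1, d2) = 4K [ (a−2d1) L(d1) − (a−2d2) L(d2) ]
                  / [ (a−2d1)² − (a−2d2)² ],
      L(d) = ln((a−d+1)/(d+1))

- whole-field mean, `R(0, a/2)`:

      %GM = 4K ln(a+1) / a

Because every mean is proportional to `K`, a single observed perimeter
mean at any depth calibrates the whole field (`calibrate` is one
division, and the calibration round-trip is exact). As `a → ∞`,
`Kbar(d)/Kbar(0) → 1/(d+1)`, recovering the elementary decay the model
was built from; finite fields decay *more slowly* than the hyperbola
(the normalized curves approach it from above as `I` grows).

All closed forms are verified in the test suite against brute-force
quadrature of `rho` (2-D for region/field means, dense line integrals
for perimeter means) to relative error < 1e-6 for `a` in {10, 50, 120,
700}, plus a conservation identity (perimeter means weighted by ring
circumference integrate to the field mean).

## Estimators

**Single-ring** (`estimate_single_ring`): calibrate on `K_d` — in
practice the pooled mean of 8 periphery samples at depth `d` (3 m by
default; 6 or 8 m surveys use the same route) — and return the field
mean. On fields generated by the pure flow model, fed the exact ring
mean, it is exact to numerical precision. It attributes everything to
border inflow, so GM of internal origin (seed admixture, volunteer
plants), which raises `K_d` by its full amount but is uniform rather
than border-concentrated, ends up roughly halved in the estimate.

**Two-part** (`estimate_two_part`): split the field into the 10 m-wide
peripheral ring (area `A_R`) and the central portion (`A_C`). The ring
mean is well approximated by the 3 m perimeter mean (`R(0,10) ≈ Kbar(3)`
within ~10% across field sizes — tested), and the central portion is
valued at the measured centre sample `K_c`:

    %GM = (K_3 · A_R + K_c · A_C) / A_T

`A_R = 10 p − 400` exactly for a square and approximately otherwise;
with an outline supplied, exact inner-offset areas (polygon buffering)
are available instead. For small fields where the approximation exceeds
`A_T`, `A_R` is clamped to `A_T` (the estimator degenerates to `K_3`,
keeping the weighted average well defined). The centre sample sees
internal GM at full strength, so the two-part route detects admixture;
for `I > 67` m the central term tends to overestimate by ~`0.0002·I` %,
which is reported as a warning and not corrected (cross-pollination
rarely reaches the centre of such fields).

The central value is taken directly as `K_c`. A blended central value
depending on both `K_3` and `K_c` is conceivable, but the plain centre
sample reproduces both published worked results exactly after rounding
and keeps the admixture signal undiluted.

**Internal contribution**: `max(0, two_part − single_ring)` estimates
the internally originated share (floored — a negative difference has no
physical meaning). On pure-flow fields the two estimators are coherent
and the difference ≈ 0.

**Sample size**: binomial kernel count `n = z² p (100−p) / E²` (percent
scale) converted to cobs; defaults `z = 1.95`, 189 kernels/cob, under
which estimating 0.9% within ±0.1 needs 180 cobs — the motivation for
the 20-cob samples of the simplified design.

## Thresholds

The empirical ceiling on border pressure is `K0_max = 10.625%`: half of
the 21.3% cross-fertilization measured (via the xenia kernel-colour
marker) around a receptor completely surrounded by a synchronized donor,
since a hemizygous cross-pollinated kernel carries half the transgene
dose of the homozygous MON810 donor. The value is stored verbatim as
printed rather than recomputed (21.3/2 = 10.65; the printed constant is
kept as the reference).

- `max_gm(I)`: calibrate at `d = 0` to `K0_max`, return the field mean —
  strictly decreasing in `I`.
- `protective_index`: invert `max_gm` at the labelling threshold by a
  bracketed Brent solve on [1e-3, 1e4] m, absolute tolerance 1e-3 m,
  reported to 0.1 m. With the defaults (10.625%, 0.9%): 62.2 m.
- `interior_after_strip`: mean over `[w, a/2]` after calibrating from a
  border or depth observation — the value of the harvest left after the
  peripheral ring is commercialized separately. At `I = 43`,
  `K_0 = 10.625%`, stripping 3 m leaves 0.9%.
- `strip_rule` (`I > 43 or K_3 < (1+I)/22`): kept as the published rule
  of thumb and documented as a heuristic. The first clause is consistent
  with the exact interior calculation (tested over `I ∈ [43, 200]`); the
  second is stricter than an exact model-based bound would be (at
  `I = 43` the model would tolerate `K_3 ≈ 3%`), so it errs on the safe
  side; its exact provenance is not derivable from the model and it is
  not used in place of the exact calculation anywhere.

## Sampling designs

**Standard (28 samples, 3 cobs each)**: four transects through the field
centre forming two perpendicular pairs, at 22.5°/67.5°/112.5°/157.5° so
border intersections land at generic positions (not rectangle corners),
mirroring the ~50–60 m field spacing. Each of the 8 transect ends is
sampled at depths 0, 3 and 10 m (samples are placed where the
*distance to the border* equals the nominal depth, found by bisection
along the transect) and each transect contributes one crossing sample at
the centre, whose depth is the true centre-to-border distance (the
half-width for rectangles). Aggregation follows the published grid rule:
ring × sector sub-areas (rings bounded by the depth contours via inward
polygon offsets, split evenly over the 8 sectors), each valued at the
mean of its 4 vertex samples, combined as an area-weighted mean.

Vertex averaging is a trapezoid rule on a convex, decreasing profile, so
the standard grid *overestimates* on model fields (~13–16% in our
layout; the published method comparison reports the same direction, a
simplified-vs-standard regression slope of 0.82, i.e. ~18–22%
discrepancy). The suite asserts the sign (standard ≥ single-ring on
noiseless model fields) and a 25% band, not a tighter one — the bias is
a property of the published aggregation rule, not an implementation
artifact.

**Simplified (9 samples, 20 cobs each)**: 8 periphery points at equal
arc spacing `p/8` (offset half a gap to avoid corners), moved inward to
depth `d`, plus one centre sample. Pooling is exact equal-mass mixing —
the arithmetic mean of the 8 sample values — and qPCR error applies once
to the pooled value (two analyses per field in total). Eight-point
sampling of a non-constant periphery slightly undersamples the hot
corners (~5% low on a uniform-pressure square); this is a property of
the field protocol itself and is part of what the noisy-recovery test
measures.

**Transect normalization**: transects that are zero at every depth are
discarded (counted), each value is divided by its transect mean so all
transects weigh equally, per-depth means ± SE are rescaled to border
= 1 and compared against `Kbar(d)/Kbar(0)`.

## Simulator

The generator reproduces the three documented variability layers:

1. *Geometry of donor pressure*: each boundary segment carries its own
   source strength `V0_i` (percent); a cob at distances `d_i` from the
   segments sees `admixture + Σ V0_i/(d_i + 1)`. With equal strengths on
   a square this is exactly the model density, giving noiseless truth
   for estimator validation. Rectangles have closed-form true field
   means; arbitrary polygons fall back to planting-lattice averages.
2. *Cob-level dispersion*: gamma draws with mean equal to the local
   surface and constant CV anchored at the observed (0.9%, SD 0.6)
   pair, i.e. CV = 2/3, gamma shape 2.25. The distribution family and
   the constant-CV scaling are modelling choices (only the one SD
   anchor is documented); gamma is the standard non-negative
   mean-parameterized choice.
3. *qPCR error*: multiplicative lognormal with mean-one factor and
   CV = 0.20 (the documented RSD ceiling), censored to 0 below the
   0.01% LOD (sub-LOD survey entries are usable as ≈0) and flagged
   approximate below the 0.3% LOQ.

Defaults are the documented study conditions: SD 0.6 at 0.9%, RSD 0.20,
LOD 0.01%, LOQ 0.3%, 3-cob standard / 20-cob simplified samples, 0.75 m
× 0.15 m planting lattice (agronomic convention, configurable). All
stochastic paths take a `numpy.random.Generator`, so runs are exactly
reproducible under a fixed seed.

What the simulator does **not** emulate: wind and anisotropic dispersal,
flowering-synchrony dynamics, landscape configuration beyond per-side
strengths, within-field heterogeneity of the local pollen cloud, or
spatial correlation of cob noise. Passing tests therefore show the
estimators behave correctly *under the model's own assumptions plus the
documented noise levels*, not that the 1/(d+1) kernel is the right
physics for any particular field.

## Validation experiments (run by the test suite)

Problem sizes were chosen to exercise the estimators across the survey's
field-size range at modest cost:

- *Parameter recovery*: 200 rectangles (60–300 m sides), per-side
  strengths U(0.2, 3.0)%, full noise; simplified protocol; median
  |relative error| of the single-ring estimate < 25%, and with the
  exact ring mean substituted for the pooled measurement the mean
  signed error sits within the Monte-Carlo error of the noisy ensemble
  (measured bias ≈ −0.3%, from shape misspecification of non-square
  fields — the equivalent-square assumption in action).
- *Donor identification*: 500 single-donor fields (donor side strength
  2.0%, ambient 0.05%, full noise); the top periphery sample flagged by
  the `value > max(LOD, 2 × median)` screen faces the donor side in
  ≥ 95% of runs (measured: 100%). The α·median screen is package
  plumbing — the published workflow identifies direction but states no
  rule — with α and the floor configurable and logged.
- *Design comparison*: paired noiseless surveys reproduce the direction
  of the published standard-vs-simplified discrepancy (slope < 1).

## Decision workflow

`decide` runs: single-ring estimate from the pooled value; two-part
estimate when a centre value exists (it governs, because it captures
internal-origin GM that the single-ring route halves — the worked
contrast is 1.13% vs 0.65% around a 0.9% threshold); label decision by
comparison with the threshold (default 0.9%, overridable per
jurisdiction); optional donor-side screen over the 8 individual
periphery values; internal/external attribution with an
"internal-origin suspected" flag when the internal share exceeds 25% of
the total (configurable). Every branch taken is recorded in an audit
trail and logged at INFO, since the output may feed regulatory
decisions.

## Numerical and degenerate-input choices

- Percent scale (0–100) everywhere; never silently converted to
  fractions.
- `Kbar(d)` switches to the centre value when `a − 2d < 1e-12 · a`; the
  closed form is continuous there, so the switch is only a guard against
  0/0.
- Perimeter line integrals ignore the four corner points (measure zero).
- Geometry validation: positive area and perimeter, the isoperimetric
  bound `A ≤ p²/(4π)`, and 0.1% consistency between stored values and an
  attached polygon. Polygons are simple rings without holes,
  orientation-insensitive.
- Ring-partition clamping (above); `w·p − 4w² < 0` is rejected as an
  invalid width.
- Regression over identical simulated fields is reported as undefined
  rather than NaN.

## Known limitations

- The equivalent-square reduction is exact only for squares; elongated
  fields carry a small shape bias (sub-percent in the recovery
  experiment's aspect-ratio range, growing with elongation).
- Point estimates only: the published method provides no interval
  estimates for the field-level estimators, and neither do we (the
  binomial helper covers kernel-sampling error only).
- The survey table bundled with the package reproduces printed inputs;
  rows whose printed estimates are inconsistent with their own tabulated
  `K_d` (the 6/8 m seasons and field 149, where the published numbers
  came from the pooled qPCR reading) are marked in a `note` column and
  excluded from reproduction tests.
- Concave polygons are accepted but depth placement assumes the
  distance-to-border grows monotonically toward the centroid; strongly
  non-convex outlines should be supplied as polygons and checked.
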