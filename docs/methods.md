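# Methods

This note documents the models, conventions, and numerical choices behind
`skeletochron`, in the order data flows through the package.

## Section geometry

A traced boundary is a simple closed polygon in mm, stored
counter-clockwise with the first vertex not repeated; input in other
conventions is normalised on construction, and degenerate input (fewer
than three vertices, zero area, self-intersection detected by shapely's
validity test) is a hard error, not a warning.

Perimeter, area, centroid, and second area moments are evaluated with the
closed-form Green's-theorem polygon formulas. The cortical annulus is
handled by signed composition: moments of the outer boundary minus moments
of the medullary boundary. The centroid and principal axes are therefore
those of the **cortex only**, not of the full section — the medullary
cavity is not bone, and for the drifted cavities in real material the two
conventions differ measurably. This is a deliberate convention choice; the
four-ray thickness *differences* (the quantities the growth analysis
uses) are nearly insensitive to it because a common reference point
cancels.

Principal axes are the eigenvectors of the areal variance tensor
[[∫x'², ∫x'y'], [∫x'y', ∫y'²]] about the centroid; the major axis is the
larger-variance direction, its sign fixed to the positive-x half-plane
(positive y on the boundary), and the minor axis is the major rotated
+90°. An isotropic tensor (circular sections, eigenvalue gap below 1e-9
relative) falls back to the +x/+y frame so that four-ray means are
reproducible run to run.

Radial thickness casts four rays from the annulus centroid along
±major/±minor and takes the nearest boundary crossing per ray; their mean
is the cumulative cortical radial thickness Tₙ at mark n. Ray-edge
intersection uses a half-open edge interval with a 1e-9 tolerance so a ray
passing exactly through a shared vertex is counted once. Star-convexity
about the centroid is assumed; if a ray crosses the boundary more than
once the nearest crossing is used and a warning logged (real diaphyseal
sections are near-convex).

## Growth records

Statuses are explicit sentinels (`fully_traceable`, `not_fully_traceable`,
`not_observed`, `not_measured`) rather than empty cells, so the *reason*
for a missing measurement survives file round-trips. Traceable
circumferences must increase strictly from the innermost mark to the
surface; the medullary boundary is excluded from this check because cavity
drift can legitimately make its perimeter exceed inner-mark perimeters
(the packaged coracoid data show exactly this).

**Mark-loss assessment** is a strict inequality: a bone may have lost
inner marks iff its medullary circumference exceeds the homologous
hatchling bone's diaphyseal circumference. Equality is not loss.

**Narrow-zone detection** flags adjacent mark pairs whose thickness
increment is below θ (default 0.5) times the element's median annual
increment. The median pools every measurable annual increment — consecutive
mark pairs, the first year when a hatchling baseline is supplied, and the
final mark-to-surface zone unless it is a flagged partial year — because
with only three or four marks a median over mark pairs alone is dominated
by the narrow zone itself. θ is configurable; 0.5 separates an unusually
long hiatus from ordinary year-to-year variation in the packaged data and
in simulation.

**Retrocalculation** aligns an incomplete record to a complete reference
record of the same individual. When both records show exactly one detected
narrow zone, the landmark years are aligned (missing = difference of the
pair-opening indices); otherwise, or when zones are ambiguous, the
mark-count difference (floored at zero) is used with a logged warning. A
reference itself flagged for loss is rejected.

**Partial final year.** A growth mark very close to or merging with the
periosteal surface bounds a zone of less than a year. The flag is an
observation made at tracing time; when the record carries an explicit
annotation it is authoritative. Only for unannotated records (synthetic or
freshly measured contours) does the package infer the flag from the
relative gap between the outermost mark and the surface (< δ, default
0.05). The δ rule is deliberately not applied over an explicit negative
annotation: a genuinely slow final year can produce a small gap that is
nonetheless a full year of growth, and only the analyst can tell the two
apart at the microscope.

## Annual quantification

Year 0 is the hatchling baseline; its "increment" is the neonate cortex
itself and is never converted to a rate (embryonic growing days are
unknown). Interior increments require the year-adjacent predecessor; a
mark bounded by an unmeasured neighbour propagates absence to both
adjacent annual entries. The surface increment bridges to the outermost
retained measured mark: outer gaps (an unobserved or untraceable final
mark) do not orphan the final zone, but inner losses leave the early years
absent. When the partial-year flag is set *and* the outermost mark lies
within δ of the surface, that mark merges with the surface: it is dropped
from the annual series and the final increment spans from the previous
mark. A decreasing cumulative series is a data-integrity error (resorption
of measured cortex is not modelled).

Apposition rate is 1000·ΔT/D µm/day with D = 214 growing days per year by
default (the annual activity season of a Louisiana alligator); D is
configurable and rates scale inversely with it. Report output rounds
half-up to 2 decimals; internal computation is full precision. Cumulative
growth curves plot the measured cumulative value at every year with a
defined increment, so records with resorbed inner marks start detached
from the origin.

## Bilateral comparison

Paired t-tests compare left−right differences of mark and surface
circumferences per element: |mean difference|, sample SD (n−1), two-tailed
p with n−1 df, and the 95% CI half-width t₀.₉₇₅,ₙ₋₁·sd/√n. Elements with
fewer than two mutually traceable levels are skipped (logged). Zero-SD
differences degenerate the test; p is reported as 0 (nonzero mean) or 1
(zero mean) with a flag. No multiple-testing correction is applied, and α
defaults to 0.05; both choices mirror the study design this reproduces.

The pooled regression fits right on left by OLS. By default it pools
**every mutually measured circumference** — medullary, hatchling, marks,
and surface — across individuals and elements; recomputation shows this is
the point set whose fit matches the published bilateral plot to printed
precision, whereas marks-plus-surface alone gives a visibly different
intercept. `regression_levels="marks"` restricts the pool to the t-test
pairs for users who prefer growth-record levels only. Note that hatchling
points are identical left/right by construction (one neonate measured
once), so including them slightly flatters the fit; both variants are
reported in the test suite.

## Synthetic skeletons

The generator emulates the study conditions: eight elements whose mean
annual radial increments order femur > tibia ≳ humerus > ulna > radius ≈
fibula, hatchling base shapes sized from neonate circumferences (r₀ =
C/2π), five growth years, lognormal annual increments (σ = 0.25, positive
by construction), and independent multiplicative left/right measurement
noise (σ = 0.01, truncated at ±2σ). Noise is applied per side to the base
shape and to each annual increment, so nested boundaries remain nested
under any realistic noise level; a configuration whose noise produces
non-nested contours raises a generation error.

Each year-k boundary is the element's base shape — an ellipse-like radial
function with small random third/fourth-harmonic perturbations — dilated
radially by the cumulative increment, which makes every contour
star-convex about the construction centre. The section is modelled as
sampled at the end of the final growing season: marks 1..n−1 lie in the
cortex and the surface ends year n, so the surface increment is the final
year's growth. With `partial_final_year` the final mark has formed and the
surface adds only a 3% sliver beyond it.

Medullary resorption is a circular front centred at the construction
centre, advancing at the configured rate scaled per element (largest for
the femur, smallest for the radius — the element that empirically retains
complete records). Marks wholly inside the final front are deleted and
counted as resorbed; marks the front cuts across are emitted as
`not_fully_traceable` placeholder rows (they occupy an index but carry no
measurements), exactly like partially resorbed marks in real sections. The
front is capped just inside the thinnest part of the surface, since a
cavity cannot engulf its own cortex. An optional narrow-zone year
multiplies one increment by 0.3, reproducing the closely spaced mark pair
used as a retrocalculation landmark.

What the generator does **not** emulate: medullary drift (the front is
concentric), secondary remodelling, element-specific tissue organisation,
and tracing errors that are correlated around a contour. Passing tests
therefore demonstrate the pipeline's correctness on near-ideal sections
with known truth, not robustness to strongly drifted or remodelled
material.

## Problem sizes and determinism

The test suite validates geometry against a grid-rasterization oracle
(0.005 mm cells) on 100 random nested sections, with principal-axis angles
compared only where the eigenvalue gap exceeds 25% — below that the axis
direction is ill-conditioned for any estimator, the oracle included.
Parameter-recovery runs use 100 simulated individuals (all eight elements,
both sides), recovering per-element mean increments to well under 1% of
the realized truth; resorption scenarios for k = 0–3 destroyed marks use
deterministic increments (σ = 0) so the dialed front position realizes
exactly k for every seed. All randomness flows through explicit seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
byte-identical output tables.

## Known limitations

* Thickness analysis follows the left-side records, as the packaged study
  measured thickness on left elements only.
* Scapula and coracoid blades drift too much for centroid-based thickness;
  they carry circumference/area records and enter the bilateral analysis,
  but not the rate tables — matching the source data, which provide no
  thickness for them.
* Retrocalculation is validated against synthetic truth only; the packaged
  study does not state how many marks any specific element lost.
* Published rate tables were computed from unrounded intermediates; a few
  cells can differ from values recomputed off the printed 2-dp columns by
  up to ~0.04 µm/day, which the validation tolerances account for.
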