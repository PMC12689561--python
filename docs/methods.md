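# Methods

## Measurement model

The package estimates ascorbic acid from a single top-down RGB photograph
taken at a controlled distance, under three assumptions:

1. **Fixed geometry.** A linear scale `px_per_cm` (default 143.79 px/cm)
   converts pixel counts to cm². The scale is valid only for the distance
   at which it was calibrated (30 cm); deviations introduce proportional
   area errors that propagate through every downstream quantity, which is
   why the scale is a config field and never hard-coded.
2. **Near-spherical fruit.** Camu-camu is close to spherical, so the
   projected silhouette is close to elliptical. When only a bounding box
   is available, the region area is taken as the inscribed ellipse
   π·w·h/4; a bare box would overestimate a round fruit by 4/π (~27%).
   Instance masks, when present, take precedence.
3. **Stage-homogeneous chemistry.** Within a ripeness stage, concentration
   is taken as the certified per-stage laboratory value; the system only
   rescales it by estimated mass. Stages follow NTP-NA 0085:2011.

### Pulp model

Default estimator: `P = a2·A² + a1·A + a0 + aM·M` with
(a2, a1, a0, aM) = (0.084, −0.252, 6.292, 0.63) g-units, calibrated against
manual depulping of 100 g samples stratified by stage and projected-area
class (the table ships as `data/pulp_yield_by_stage_and_area.csv`). The
maturity factor maps the commercial stages in ripeness order: Pinton
Green → 0, Ripe Pinton → 1, Ripe → 2. This mapping is the natural ordinal
one but is a config field, since only the codomain {0,1,2} is fixed by the
calibration. Notes on the model's shape:

- The vertex of the quadratic sits at A = 1.5 cm²; below it the model is
  flat-to-decreasing, and its intercept (6.292 g at A = 0) is biologically
  odd. The model is evaluated as calibrated over A ≥ 0 without domain
  restriction — it was fitted for whole-fruit areas (~4–10 cm²), and the
  package does not extrapolate to negative areas.
- Area-class boundaries ("less than 5", "between 5 and 8", "more than 8")
  are resolved half-open: [0,5), [5,8), [8,∞). The boundary convention is
  not observable in the calibration data; half-open intervals partition
  [0,∞) cleanly.
- The slab-volume alternative (`P = A·t·ρ`, t = 0.8 cm, ρ = 1 g/cm³)
  remains selectable (`--pulp-model thickness`); it covers Green fruits
  too, which have no maturity factor.

### Concentration scaling

`R2 = R1 · b2 / b1` with b1 the 100 g laboratory reference mass. Per image
and stage, b2 is the summed estimated pulp mass of that stage's fruits —
the aggregation that makes the per-stage system value comparable with a
per-100 g laboratory value. Per fruit, total ascorbate is `R2/100 · m_pulp`
mg; the per-100 g concentration and the per-fruit milligram total are kept
as distinct report fields.

### Error analysis

MAPE per stage, unweighted mean over the commercial stages (Green is not
commercialized and is excluded by default; including it requires an
explicit flag and warns). Human-facing tables round half-up to the printed
decimals; machine outputs keep full precision.

## Reference detector

The built-in detector exists so the chain is runnable and testable without
trained weights; it is a deliberately simple baseline, not a reimplementation
of a learned model. Foreground = HSV saturation above 0.15 (the neutral
background is near-gray); connected components above a minimum area
(default: the pixel equivalent of 0.1 cm² at the configured scale) become
detections with mask, tight bbox and confidence 1.0. Staging embeds the
region's mean color as (S·cos 2πH, S·sin 2πH, V) — Euclidean-comparable,
no hue wrap-around, insensitive to brightness changes at fixed hue and
saturation — and picks the nearest of four prototype colors, ties broken
toward the lower ordinal. The palette is a fixture chosen to span green →
yellow-green → orange-red → dark red; stage colors are defined visually,
not numerically, in the field, so prototypes are user-configurable.

Touching fruits are not split (no watershed): the synthetic generator
guarantees non-overlap, and overlap handling belongs to external learned
detectors, whose outputs can be loaded as COCO JSON instead.

## Synthetic scenes

The generator emulates the acquisition geometry the calibration assumes:
~15 fruits per frame on a neutral background, four stage colors, fixed
linear scale. Defaults: 1024×1024 canvas standing in for the native
3024×3024 capture, with `px_per_cm` scaled by the same factor
(143.79 × 1024/3024 ≈ 48.69) so physical areas — and everything downstream
— are preserved while keeping rendering and segmentation seconds-scale;
uniform stage mix; fruit diameters 2–3 cm (≈10 fruits per 100 g reference
sample implies ~10 g, near-spherical ≈ 2.7 cm); rotated ellipses with
aspect ratio 0.85–1.0. One `numpy` generator seeded from `spec.seed` drives
every draw, so scenes are byte-reproducible. Optional degradations:
additive Gaussian noise, specular highlight spots, Gaussian blur, per-fruit
color jitter.

Ground truth stores each ellipse's analytic area π·a·b and the pulp mass
and R₂ the calibrated pipeline should report. What synthetic scenes do not
emulate: 3-D shading, occlusion and touching fruit, background clutter,
stage-internal color gradients, camera-distance miscalibration. Passing the
end-to-end recovery test therefore validates the measurement chain's
arithmetic and the detector's contracts — not detection or staging
performance on real photographs, which requires real, annotated images.

## Numerical choices

- End-to-end tolerance 2% for synthetic recovery: rasterized ellipse masks
  differ from π·a·b by O(perimeter) pixels, well under 2% at the default
  fruit sizes (~60 px radius); the pulp polynomial's local slope (~0.6 g/cm²
  near 5 cm²) keeps the propagated concentration error below the same bound.
- Detection matching: greedy one-to-one by descending confidence, then
  descending IoU, at a single IoU threshold (default 0.5). For
  non-overlapping ground truth at threshold ≥ 0.5 a prediction can clear
  the threshold with at most one truth box, so greedy matching attains the
  optimal assignment; the test suite checks this against an exhaustive
  oracle. mAP over threshold sweeps is out of scope — the reference
  detector emits constant confidence.
- Ties in staging (exactly equidistant prototypes) resolve to the lower
  ordinal, making classification deterministic.
- Rounding for printed-table comparison is decimal half-up, not banker's.
- Empty inputs are data, not errors: an image with no fruits yields a
  zero-total report; empty prediction sets yield precision 0 against
  non-empty truth, and all-empty detection instances count as vacuously
  perfect.

## Limitations

- The certified concentrations and the pulp calibration are specific to
  camu-camu and the documented acquisition geometry; transfer to other
  crops or distances requires recalibration.
- The quadratic pulp model's coefficients cannot be re-derived from the
  shipped depulping table alone (per-fruit areas within each stratum are
  unknown); the suite's refit test checks regression stability with
  declared representative areas, not coefficient agreement.
- The reference detector assumes a neutral background and non-touching
  fruit; field images with clutter or occlusion need an external detector.
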