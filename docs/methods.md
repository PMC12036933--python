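# Methods

`somamorph` reimplements, as a tested pipeline, the quantitative core of a
juvenile-songbird neurogenesis study design: soma morphometry on traced 2-D
contours, unbiased grid subsampling, profile-density and Cavalieri-volume
stereology, and the bird-level group-comparison statistics — together with a
hierarchical synthetic-study generator that provides ground truth for
validating every stage.

## Soma descriptors

A traced soma is a simple closed polygon with vertices in µm, stored open
(the closing edge is implicit) and oriented counter-clockwise. From it we
compute area *A* (shoelace), perimeter *P*, the maximum Feret diameter
`F_max` (caliper diameter) and minimum Feret diameter `F_min` (width), and
five dimensionless descriptors:

- aspect ratio `F_min / F_max` — flatness; 1 for a circle, smaller for
  flatter somata;
- compactness `√(4A/π) / F_max` — the equivalent-circle diameter relative
  to the caliper diameter;
- roundness `4A / (π F_max²)` — identically compactness squared; spreads
  out small compactness values;
- shape factor `P / √A` — large-scale boundary convolution; minimal at
  `2√π ≈ 3.54` for a circle (isoperimetric bound);
- form factor `4πA / P²` — fine-scale boundary roughness; 1 for a circle
  and strictly below 1 for any other simple contour.

Aspect ratio is defined min-over-max so its range is (0, 1] and flatter
means smaller, consistent with how the flatness scale is described and
plotted in the source field conventions; compactness and shape factor are
the unique dimensionally consistent forms that hit the printed circle
anchors (compactness 1, shape factor ≈ 3.54) and satisfy
roundness = compactness².

Feret diameters are computed on the convex hull of the vertex set — the
diameter and width of a polygon equal those of its hull — by a single O(h)
rotating-calipers sweep: for each hull edge the antipodal pointer advances
to the vertex farthest from the edge line; the diameter is the maximum
distance over the antipodal pairs visited and the width the minimum
farthest-vertex edge distance. Both are exact (the width of a convex
polygon is attained flush to an edge); the test suite checks them against
brute-force all-pairs and per-edge oracles on 1000 random simple polygons.

Degenerate inputs (fewer than three distinct vertices, self-intersection,
zero area) are rejected rather than repaired: silent repair would bias the
morphometrics. Vertices closer than 1 nm are treated as duplicates.
Contours are measured as traced polygons; no smoothing or spline
interpolation is applied.

## Grid subsampling

The non-birthdated Hu+ population is subsampled with a square grid
(default 100 µm squares) anchored at the top-left corner of the region
tracing's bounding box and covering it completely. Every fourth square in
row-major order is selected, with the row-start offset cycling by one
column per row (`(col − row) % 4 == 0`), which selects ≈ 25% of squares
without column-aligned stripes. A cell is sampled when its marker point
falls in a selected square *and* its traced contour neither crosses nor
touches that square's top or left edge; the right and bottom edges are
acceptance edges. This complementary forbidden/acceptance-edge convention
is the standard unbiased counting-frame rule: a cell straddling a boundary
is countable in exactly one square, so nothing is double-counted or
systematically lost. Each marker is evaluated only against the square
containing it. A fixed-seed random-offset origin mode exists for
demonstrating unbiasedness (the sampled fraction of uniformly scattered
small cells converges to the selected-square fraction).

The grid origin, stride pattern, and the use of the full contour (rather
than the marker point) in the edge rule are conventions of this package,
chosen where the design leaves them open; they are deterministic and
auditable (`sample_table` records the decision for every marker).

## Stereology

Areal densities are pooled: total labeled cells over total sampled area
across sections (cells/mm²), not the mean of per-section densities — the
pooled ratio is the design-unbiased choice when section areas vary.
Region volume is the Cavalieri estimate `Σ areas × thickness × interval`
(6 µm sections, every 8th collected). Total cells per region default to
the dimensionally consistent form: areal density is converted to a
volumetric density by dividing by section thickness before multiplying by
volume and rounding. Because the field sometimes reports the plain
areal-density × volume product, a `literal` mode reproduces that
arithmetic unrounded; outputs are labeled by mode. No Abercrombie or
profile-count correction is applied. The module accepts any number of
section areas for the volume but warns below five (the design measures
~20 evenly spaced sections).

## Statistics

The bird is the unit of analysis: each bird contributes the unweighted
mean of its cells' values per descriptor and population (cells per bird
vary ~13–100; count-weighted means are available but off by default).
Group comparisons use pooled-variance Student t-tests, df = n₁ + n₂ − 2
(11 for 6 vs 7 birds) — pooled rather than Welch is a fidelity choice to
the study design being modeled and is visible here deliberately, since
group variances are not guaranteed equal. The two populations within the
same birds are compared with a 2 (group) × 2 (population) mixed ANOVA
implemented as an explicit sums-of-squares decomposition: the group effect
is tested against the subject-within-group stratum and the population and
interaction effects against the subject × population stratum; with
unbalanced groups the marginal means are group-size weighted (verified
against an independent implementation, pingouin, in the tests). Post-hoc
paired t-tests compare populations within each group.

Descriptor families (five dimensionless descriptors plus area and both
Feret diameters, per population) are corrected with the
Benjamini–Hochberg step-up FDR; raw p-values are always retained next to
adjusted ones, since which flavor a given report prints is often
ambiguous. Covariate screens (age at treatment start, treatment duration,
age at first BrdU, age at perfusion against densities, and against
morphology within the treated group) use OLS with the two-tailed slope
t-test, run within each group and combined.

## Synthetic data

The contour model is a radial Fourier ellipse:
`r(θ) = ellipse(θ; q) · (1 + Σ aₖ cos(kθ + φₖ))`, with axis ratio `q`,
harmonic amplitudes drawn from two bands — convolutions k ∈ [2, 6] and
roughness k ∈ [12, 40] (band edges are conventions, configurable) — each
band's per-harmonic SD set to `amp/√(n_harmonics)`. The polygon is sampled
at 256 equally spaced angles, randomly rotated, and rescaled to the target
area exactly. Because the radius stays positive on a strictly increasing
angle grid, the polygon is star-shaped and therefore simple by
construction; draws whose radius dips non-positive are resampled (at most
100 times). This model was chosen because its four axes map one-to-one
onto the descriptor families the pipeline measures.

A full study draws, per bird: covariates from the experimental ranges
(treatment start 18–49 d; first BrdU 75–79 d; perfusion 32 d later;
duration the difference, 62–92 d); 10–12 sections per region with smooth
~0.35 mm² outlines; a birthdated population (counts from a discretized
log-normal clipped to [13, 100], mean ≈ 40, σ_log = 0.6 — matching the
reported range, mean and right skew) traced in HVC; a non-birthdated Hu+
marker population of about four times its intended traced count (13–100 ×
the grid rule's ≈ 1/4 acceptance reproduces the reported 14–66 traced,
mean ≈ 38); and DCX+ point markers at 300 cells/mm² in both regions.
Baseline soma parameters: birthdated cells 70 µm² mean area, axis ratio
0.75; the older heterogeneous population 100 µm² and 0.78 (the older
population is larger, as observed). Cell positions are uniform within
section outlines.

Group effects are declared per `(population, field)` as additive or
multiplicative deltas applied to the treated group; the preset
"reported-direction" pattern is axis ratio −0.06 and roughness amplitude
+0.03 in the birthdated population, area ×0.9 in the older population,
and no density effect. Bird-level random-effect SDs (axis ratio 0.030,
roughness 0.012, convolution 0.008, log-area 0.055) and cell-level jitter
SDs (0.080 / 0.020 / 0.015 / 0.250) were fixed once, at design time, so
that at those deltas the simulated bird-level t statistics land near the
|t| ≈ 2.8–3.1 magnitudes the modeled study reports for 6 vs 7 birds; they
are study conditions, not free dials.

All randomness flows from one study seed through named substreams
(covariates, sections, and each bird × region × phenotype cell stream),
so regenerating any component is independent of the others, and
regeneration at the same seed is byte-identical through file round trips.

What the generator does *not* emulate: histological shrinkage and
processing artifacts, optical z-axis effects (sections are treated as 2-D
profiles, as in the design), spatial clustering of cells, non-Gaussian
bird effects, and tracing error. Passing recovery tests therefore shows
the pipeline is correct and well calibrated under the declared hierarchy,
not that real tissue meets those assumptions.

### Calibration and recovery checks

- Type-I error: bird-level t-tests on null-generated studies reject at
  5% ± 1.5% over 2000 simulated studies. This check runs on the
  generator's analytic bird-mean sampler (`gen_bird_mean_samples`), which
  draws the identical hierarchy (group mean + bird effect + cell-jitter
  mean over the drawn cell count) without rendering contours — the t-test
  only ever sees bird means, so rendering adds nothing to this check.
- Effect-direction recovery: over 200 seeded full studies at the
  reported-direction preset, the rendered pipeline (contours → descriptors →
  grid sampling → densities → bird summaries) recovers the complete
  pattern — treated birds flatter and rougher in the birthdated
  population, smaller in the older population, with a non-significant
  density difference — in ≥ 80% of studies (observed ≈ 95%+). "Recovers a
  direction" means the sign of the group mean difference matches the
  declared delta; the density check asks the t-test *not* to reject.

## Numerical choices and edge cases

- Coordinates are µm throughout geometry; mm²/mm³ conversions happen only
  in the stereology module.
- Duplicate-vertex tolerance 1e−9 µm; area rescaling in the generator is
  exact (multiplicative).
- Markers exactly on an internal grid line belong to the square
  right/below (floor convention); the outer right/bottom grid boundary is
  folded into the last square.
- Zero pooled variance with unequal means raises a degenerate-variance
  error instead of returning ±∞; with equal means it returns t = 0, p = 1.
- Study files store coordinates at 0.01 µm; the marker-inside-outline
  validation allows that much slack. Write → read → write is
  byte-identical.
- t-tests, OLS and the BH procedure delegate to scipy/statsmodels; the
  mixed ANOVA and the caliper geometry are implemented here and checked
  against independent references in the tests.

## Problem sizes in the validation suite

The shipped suites use a 12,000-vertex circle for the anchor checks, 1000
random polygons (≤ 50 vertices) for the geometric oracle equivalence, 100
seeds × 5000 planted cells for stereological recovery, 2000 simulated
studies for t-test calibration, and 200 rendered studies (6 + 7 birds,
two regions, ~2500 contours each) for effect-direction recovery.

## Known limitations

- The forbidden-edge rule uses each square's own finite edges, not
  infinitely extended forbidden lines; for cells larger than a grid
  square this differs from the classical counting frame.
- The pooled t-test is not robust to strong variance heterogeneity;
  Welch's test is not currently exposed.
- The mixed ANOVA handles exactly the 2 × 2 design used here.
- The generator's density model is homogeneous within a section; no
  within-region gradients.
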