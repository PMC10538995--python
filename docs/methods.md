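# Methods

This note documents the models, algorithms and parameter choices behind
`fiberredox`, what the synthetic-data generator does and does not emulate,
and the numerical conventions that affect results.

## The measurement model

A muscle cross-section is imaged as co-registered 2-D channels (NADH and Fp
autofluorescence, MHC I and MHC IIa immunostains, DAPI, a capillary stain,
optionally collagen, SDHA and CS). All intensities are arbitrary units from
a single standardized acquisition: the package enforces exposure/gain
equality as a metadata check and refuses to pool mismatched acquisitions
unless an explicit rescale factor is configured, rather than attempting a
computational correction.

Per fiber, the measured signal is the mean of interior pixel intensities
minus a scalar background, floored at zero (arbitrary-unit intensities
cannot be negative; a floor event is visible as an exact 0). The background
is the median intensity of all pixels outside every fiber ROI after a 2-px
dilation of the ROIs; if the ROIs tile the image an explicit value is
required, and a warning is raised when less than 2% of pixels remain. The
median is used because the outside region is contaminated by occasional
bright debris in real sections. The per-fiber statistic is the mean by
default (standard densitometry); the median is available via `statistic=`.
Fibers containing any pixel at the saturation cap are flagged, not silently
dropped.

The optical redox ratio is Fp/(Fp + NADH), computed **per fiber** and then
averaged within type. Mean-of-ratios and ratio-of-means differ in general
(the test suite asserts this on a constructed counterexample); the
per-fiber convention matches how individual-fiber data are plotted and
keeps each fiber one observation. The ratio is scale-invariant, bounded in
[0, 1], strictly increasing in Fp and decreasing in NADH, and undefined
(reported missing, with a warning) when both signals are zero.

No spectral unmixing is attempted: NADPH is optically indistinguishable
from NADH and non-dehydrogenase flavoproteins contribute to Fp; the ratio
is an index of the aggregate pools.

## Segmentation and typing

Fibers tile the section and are separated by thin dark boundaries. The
max-projection of the MHC channels plus an optional autofluorescence "hint"
channel (which lights up MHC-double-negative IIx fibers) is thresholded,
holes are filled, and touching fibers are split by watershed on the
Euclidean distance transform. Two non-obvious choices:

- **Tissue threshold**: the projection is generally *trimodal*
  (background, dim double-negative fibers, bright MHC-positive fibers), so
  a plain bimodal Otsu threshold swallows the IIx fibers. The package uses
  3-class multi-Otsu and takes the lower threshold, falling back to plain
  Otsu for histograms too coarse for three classes.
- **Watershed markers**: markers are the h-maxima (h = 2 px) of the lightly
  smoothed (Gaussian, σ = 2 px) distance transform. The distance transform
  of a convex region is concave, so a single near-convex fiber produces
  exactly one marker; merged fibers show a neck whose dip exceeds h and are
  split. Marker-per-local-peak schemes oversplit elongated fibers.

Fibers clipped by the field of view (within 3 px of the border by default)
are flagged and excluded from area and intensity statistics — their area is
censored. Regions below `min_area_um2` (default 500 µm²; far below any real
myofiber) are rejected as debris.

Typing uses the median interior intensity per ROI (robust to nucleus
hotspots) against a per-channel positivity cutoff: (MHC I, MHC IIa) =
(+,−) → I, (−,+) → IIa, (−,−) → IIx, (+,+) → hybrid. Hybrids are excluded
from every downstream statistic. A score exactly at the cutoff counts as
negative (conservative positivity). The default cutoff is an exact
small-sample Otsu on the vector of per-ROI medians — every midpoint between
consecutive sorted medians is scored by between-class variance — which is
exactly equivariant under positive affine rescaling of the channel. If the
two classes are separated by less than 2 pooled SDs the distribution is
deemed unimodal and a user-supplied fallback cutoff is required.

## Capillarization morphometry

Capillaries are connected bright blobs in the capillary channel whose
equivalent diameter falls in 2–8 µm; a blob up to twice the maximum
diameter is kept as a single detection with a warning (two capillaries
merged at the resolution limit), anything larger is rejected. Nuclei use
the same detector at 3–10 µm.

The contact graph joins capillary c to fiber f when c's center lies within
the contact tolerance (default 1.5 µm) of f's boundary, or inside f. The
analyzed area is the convex hull of the included fibers — empty image
margins are not "analyzed area" — and when the area is derived this way,
capillaries outside the hull are dropped so that every density divides
counts and area of the same region. Panel definitions:
CD = N_cap/area; C:F = N_cap/N_fibers; CC = mean contact degree over
fibers; SF = CC/C:F (undefined without capillaries, reported missing);
CC/FA = mean over fibers of (degree / fiber area µm²) × 1,000. The
handshake identity (sum of capillary degrees = sum of fiber degrees =
number of edges) and SF = CC/C:F hold exactly *per section*; cohort tables
that average per-subject values need not satisfy the identity.
A capillary contacting no fiber still counts in CD and C:F.

Diffusion distances are geometric and primary: for every interior pixel,
the Euclidean distance (distance transform) to the nearest capillary; the
maximal (average) diffusion distance is the 95th (50th) percentile of that
distribution in µm — the radius within which 95% (50%) of fiber area is
served. The test suite pins this against a brute-force per-pixel
nearest-capillary enumeration to within 1 px. A legacy linear regression of
the distances on C:F and fiber area exists in the literature, but its
printed algebraic form is ambiguous (likely lost exponents in typesetting),
so the package ships **no** default coefficients: the regression evaluator
is disabled until the user supplies the exact form
(`DiffusionRegressionCoefficients(a, b, power)`, dd = a + b·C:F·FA^power),
and its output is reported in a separate labeled column, never merged with
the geometric estimate.

## The inference layer

The unit of analysis is the per-subject, per-timepoint, per-fiber-type mean
(fibers are aggregated before modeling; the random structure has
participant intercepts only, no per-fiber nesting). The model is a linear
mixed model with fixed effects for time and fiber type (optionally their
interaction, or sex in place of/alongside time) and a random intercept per
participant, fitted by REML through statsmodels `MixedLM`. Missing cells
are tolerated without dropping subjects, which is the reason for the mixed
model: histology allocation follows biopsy yield, so cells are missing at
random. Non-convergence raises with diagnostics; a singular design (factor
with one observed level) is rejected up front.

Estimated marginal means average the fixed-effect predictions over an
equally weighted grid of the other factors' levels. The fixed-effects
covariance is the model-based GLS form (X'V̂⁻¹X)⁻¹ computed directly per
group — not from the REML Hessian, which is singular whenever a variance
component sits on the boundary (the noiseless limits degrade gracefully,
with SEs → 0). Pairwise contrasts within one factor form one Tukey family:
p = P(Q_{k,df} ≥ |t|·√2) from the studentized-range distribution, with a
containment-style denominator df = n_obs − rank(X) − (n_groups − 1) as a
conservative stand-in for a Satterthwaite approximation (which the backend
does not expose). Simulation places the resulting omnibus type-I error at
the nominal 5% (4.9% over 1,000 null cohorts of 19 subjects) and the
95% CI coverage of the I-vs-IIa contrast at ≈95%.

Percent differences are ratios of marginal means, 100·(a − b)/b, with the
later-listed (less-oxidative) level as reference b — "I is 7.2% higher than
IIa" — and the CI obtained by transforming the contrast's t-interval
endpoints onto the percent scale (reference treated as fixed). Both
directions of a pair differ in general; the reference is always explicit.
Tests are two-sided at α = 0.05. Spearman correlations use average ranks
for ties (scipy backend; the suite pins it to an explicit average-rank
enumeration), drop incomplete pairs, require ≥ 3 pairs, and report a
constant input as missing.

## Cohort screening

Goldberg cutoffs with the Black adjustment bound plausible EI:BMR ratios:
with S = √(CV²_EI/d + CV²_BMR + CV²_PAL) (CVs in percent, d recording
days), bounds are PAL·exp(∓2·S/100/√n). The interval collapses to PAL at
zero CV, narrows with n and d, and satisfies lower·upper = PAL² exactly.
Bounds are treated as inclusive. Shipped defaults for the screening
*labels* are the published interval conventions (individual 0.76–2.41,
cohort 1.18–1.55); the cohort-specific CVs behind any particular published
interval are generally not recoverable, so those bounds are defaults, not
recomputed values. BMR is an input column (measured or from a
user-configured regression on age, sex, fat and fat-free mass); no BMR
equation is hard-coded. HOMA-IR uses the mass-unit convention
glucose(mg/dL)·insulin(mU/L)/405, numerically equal to the molar form
glucose(mmol/L)·insulin/22.5 within the unit-conversion rounding (<0.5%).

## The synthetic-section generator

The simulator emulates a vastus lateralis cross-section at ×20, and its
defaults are the study conditions for every test:

- **Geometry**: a Lloyd-relaxed (3 iterations) Voronoi tessellation of
  uniformly seeded points, bounded by mirroring the generators across the
  image edges, each cell eroded by 1.5 px to create the visible inter-fiber
  boundary. Cells are near-convex polygons, the standard stand-in for
  myofibers; convexity is not enforced. Defaults: 70 fibers on 896×896 px
  at 0.65 µm/px → ≈4,800 µm² mean fiber area.
- **Types**: hybrid with probability 2%, otherwise I/IIa/IIx drawn from
  (45.9, 44.5, 9.6)%. Hybrids are rendered positive in both MHC channels.
- **Intensities**: fiber interiors carry per-type means above a uniform
  background (default 100 a.u.) with additive Gaussian noise (default SD
  20 a.u.), clipped at zero and at the optional saturation cap. Default
  channel means preserve the orderings Fp: I > IIa > IIx (900/700/450) and
  NADH: I ≈ IIa > IIx (800/780/520); the absolute scales are free
  parameters — the instrument's a.u. scale is not a published quantity —
  so only orderings and ratios are meaningful. The implied planted redox
  ratios are 0.529/0.472/0.464.
- **Capillaries**: discs (2.6 µm) at Voronoi vertices shared by ≥ 2 fibers
  (anatomically, capillaries sit at fiber junctions), each kept with
  probability `capillary_retention` and subject to a 4 µm minimum
  separation so that detections remain resolvable. Junction-vertex
  placement caps the achievable C:F near 2 (a Voronoi tessellation has
  ≈ 2 vertices per cell), at the low end of the physiological 2.0–2.5
  range; retention scales it downward from there.
- **Nuclei**: Poisson(3.8) per fiber, placed on the fiber periphery with a
  minimum separation, as discs in the DAPI channel (≈780 nuclei/mm²).
- **Collagen**: an exact planted fraction (default 0.75%) of tissue pixels
  set to a stained level, enabling an exact recovery test.
- **Randomness**: one `numpy` Generator seeded from `SectionParams.seed`;
  identical parameters give bit-identical images and truth tables.

What it does **not** emulate: point-spread blur, uneven illumination,
photobleaching, 3-D sectioning artifacts, staining variability between
sections, fiber-type clustering, or the correlation between fiber size and
type observed in real muscle (simulated IIx fibers are not systematically
smaller). Consequently, passing tests demonstrate the *correctness of the
computations* under a clean, known-truth model — exact typing given
separable stains, exact geometry, calibrated inference — not robustness to
the full messiness of real histology; positivity cutoffs and the contact
tolerance in particular should be inspected on real data.

The cohort generator produces outcomes with exactly the additive structure
the mixed model assumes: grand mean + fiber-type effect + time effect
(+ sex effect) + subject intercept + residual. `default_cohort_effects()`
plants a baseline fiber-type gradient with marginal percent differences of
exactly 7.2% (I vs IIa) and 8.0% (IIa vs IIx) around a 0.47 IIa baseline,
with subject SD 0.03 and residual SD 0.02 — an ICC of ≈0.69, typical of
repeated histology outcomes. Simulated per-cell fiber counts are drawn as
round(N(65, 10)), the scale of fibers analyzable in one ×20 field.

## Numerical conventions and problem sizes

- Pixel grid is 0-based row-major (row, col); polygons use (x, y) =
  (col, row); areas in µm² via pixel_size², densities per mm², distances
  in µm.
- Percentiles use numpy's linear interpolation; the 95th ≥ 50th identity
  is therefore exact.
- Ties at a positivity cutoff are negative; ties in ranks use average
  ranks; contrasts with zero SE report p = 1 when the estimate is zero and
  p = 0 otherwise.
- The test suite runs its section-level checks on compact sections
  (320–640 px, 45–70 fibers, with `min_area_um2` scaled to the smaller
  fiber areas those sizes imply) and its inference checks on 200 simulated
  cohorts for CI coverage plus 500 null replicates for type-I error; the
  acceptance script uses full-size sections (896 px, 70 fibers, 10
  sections) and 100/300 replicates. These sizes were chosen as the
  smallest at which the binomial/Monte-Carlo error bands in the assertions
  are meaningful.
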