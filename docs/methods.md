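# Methods

This note documents the models, default parameters and numerical choices
behind `octmorph`.  Everything here is implemented and exercised by the
test suite and `scripts/acceptance.py`; no empirical claim is made beyond
what those compute.

## The eye model

A post-keratoplasty eye is modelled in a 2-D cross-sectional plane, in
millimetres, with `x` lateral (0 on the scan axis) and `z` depth
(0 at the anterior edge, increasing posteriorly):

* **Anterior cornea**: circle of radius 7.8 mm (a typical anterior
  corneal radius; not a measured parameter here), apex 0.3 mm deep.
* **Posterior cornea**: circle whose radius is the "posterior curvature"
  cohort parameter, apex 0.6 mm below the anterior apex (host stromal
  thickness after stripping).
* **Scleral spurs**: the two endpoints of the posterior corneal circle,
  at angle ±θ/2 from the apex.  By construction
  `PCAL = R·θ` and `ACW = 2R·sin(θ/2)` exactly.
* **Graft**: its posterior surface is a separate circle attached below
  the host posterior cornea, separated by the graft thickness at the
  apex; `PGAL = 2·R_g·h` and `PGCL = 2·R_g·sin(h)` with half-angle `h`.
  The anterior graft surface rides on the host posterior cornea, so
  `AGAL = R·θ_g` and `AGCL = 2R·sin(θ_g/2)`.
* **Iris**: a flat band at 3.8 mm depth (pushed deeper if a thick graft
  would touch it), with a 3.5 mm pupil, its wings kept at least 0.3 mm
  clear of the corneal flank so the angle recess stays open.
* **Sclera**: continues the anterior surface laterally; its inner wall
  leaves the spur along the posterior circle's tangent for 0.25 mm and
  then drops into a 0.25 mm spur protrusion — the spur is the point
  where the inner wall's curvature changes, as it is identified
  clinically.

### Over-determination of the printed cohort moments

The reported cohort means for PCAL (12.99 mm), ACW (11.16 mm) and
posterior curvature (5.80 mm) are mutually inconsistent for spurs lying
on a single circle: the arc/chord pair alone implies a radius near
6.99 mm.  Real peripheral corneas flatten, so all three can hold
simultaneously in vivo but not in a single-circle model.  The geometry
generator therefore treats PCAL, curvature, AGAL, PGAL, PGCL and graft
thickness as the primary draws and *derives* ACW (≈10.44 mm at the
means) and AGCL (≈8.60 mm).  The measurement-level cohort simulator
(`generate_cohort`), which does not build geometry, samples ACW and AGCL
near their printed moments instead.

### Sampling

`generate_eye_geometry` draws each primary parameter from a Gaussian
truncated at zero (bounded rejection, 10,000 tries).  Joint feasibility
(the cord/arc ratio must correspond to a half-angle below π/2, the graft
must fit inside the spurs, the spur angle below ~166°) is enforced by
redrawing only the subordinate parameters (curvature, PGCL, AGAL), so
the marginals of PCAL, PGAL and thickness remain exactly the configured
truncated Gaussians; the conditioned marginals of the others shift by
well under their Monte-Carlo noise at cohort sizes.

## Rendering

Default field: 600 × 300 pixels over 16 mm × 6 mm (26.7 µm lateral,
20 µm axial).  Tissue regions (cornea, graft, sclera, iris) render at
mean intensity 180, open space at 40.  The host/graft interface is a
0.08 mm dark cleft (interface fluid); the graft's tapering edge is cut
bluntly where the slab would thin below 0.1 mm.  These widths were
chosen so that the cleft is resolvable at the 20 µm axial pitch — a real
interface cleft can be thinner than a pixel, and eyes whose rendered
cleft is at or below resolution are precisely the ones the quality gate
excludes (see below).

**Speckle** is fully developed, single-look: every pixel is multiplied
by an independent unit-mean exponential variate, then quantised to
8 bits.  This is the harshest first-order speckle statistic (intensity
SD equals the mean); it does *not* model the spatial correlation of a
real point-spread function, log compression of display pipelines, or
multi-look averaging, all of which make real scans easier to segment.
Passing the recovery tests under this model is therefore conservative
with respect to noise statistics, while the geometry (perfect circles,
known landmarks) is idealised.

**Refraction warp** (optional) ray-traces every A-scan: straight to the
air–tear interface, Snell refraction at the local normal, optical-path
(index-stretched) depths below, a second refraction at the outer
tissue–aqueous boundary.  Default group indices: air 1.000, cornea
1.388, aqueous 1.343 (1310 nm values commonly used for time-domain
anterior-segment scanners); they are configuration, not constants.
Total internal reflection flags the column.  With all indices 1 the warp
is the identity.

## Segmentation chain

`segment_image` runs: conditioning → speckle suppression → (dewarp) →
binarisation → tracing → quality gate.

1. **Conditioning**: 3×3 median filter, then a linear 1st–99th
   percentile contrast stretch.  Near-idempotent; constant images pass
   through with a warning flag.
2. **Speckle suppression**: Gaussian spatial compounding,
   σ = (1.5 axial, 0.8 lateral) pixels.  A single-look exponential field
   leaves ~30% of tissue pixels below any global threshold after median
   filtering alone, so compounding is required before thresholding; the
   window is kept narrow laterally so the interface cleft survives where
   the surfaces run steeply.  The stage measures residual
   high-frequency noise first and passes clean images through untouched.
3. **Dewarp**: inverts the forward refraction model using the traced
   air–tear interface (imaged undistorted) and the traced outer tissue
   boundary (mapped back to physical space before the second
   refraction), then resamples bilinearly onto the physical grid.
   Columns without interfaces are copied through and flagged.
4. **Binarisation**: Otsu's between-class-variance threshold, with the
   reported threshold canonicalised to the midpoint of the empty
   intensity gap between the classes.  Constant or effectively unimodal
   images raise a low-contrast error for the quality gate.
5. **Tracing** (per column on the mask, after a 3×3 majority vote and
   connected-component cleanup on speckled masks): the corneal complex
   is anchored on the longest tissue run and absorbs neighbouring runs
   across gaps up to 12 px; the epithelium is its first pixel, the graft
   posterior its last, the first run below a wider gap the iris.  The
   host/graft cleft is selected among per-column gap candidates by
   growing a support circle inward from the zone flanks (the host
   posterior cornea continues circularly under the graft), accepting
   candidates within 0.15 mm of the current fit; this keeps every
   prediction a short extrapolation.  Columns whose band bottom
   collapses onto the host circle (slab dropout), dives implausibly deep
   (speckle bridge to the iris) or spikes upward against its running
   median are excised and re-interpolated.  Boundary series are then
   smoothed: moving median plus a Gaussian low-pass with
   linear-extrapolation end padding, split at steps and at kinks
   (detected against the segment's own roughness) so sharp anatomy —
   the graft edge corner — is preserved, with raw values restored in a
   two-column neighbourhood of unmistakable corners.  Smoothing windows
   adapt to the measured mask noisiness.  The selection self-checks:
   if fewer than 40% of graft-zone columns resolve a cleft, or the
   selected cleft is inconsistent with a circle (rms > 0.06 mm), the
   trace fails and the quality gate excludes the eye.
6. **Quality gate**: an eye is included iff both spurs were identified,
   image contrast (95th−5th percentile) exceeds 30 levels, and
   binarisation/tracing succeeded; the first failure is recorded.  On
   default-speckle synthetic batches this excludes roughly 10–25% of
   eyes — dominated by thin grafts whose cleft is at or below the axial
   resolution — mirroring the ~10% of clinical scans that such software
   cannot process.

## Measurement

* Arc endpoints attach by perpendicular projection of the landmark onto
  the nearest polyline segment (sub-pixel placement), and the arc is the
  summed segment length between the projections; chords are Euclidean
  distances between the landmarks.  PCAL follows the host endothelium
  through the graft zone by default (`pcal_surface="host"`); a
  `"graft"` switch substitutes the graft posterior surface, since which
  surface a clinical tracer follows there is a convention.
* Curvature: Kåsa algebraic circle fit refined by one Gauss-Newton step,
  over the central 6 mm chord of the posterior cornea.
* Graft thickness: perpendicular distance from the graft posterior
  surface to the host/graft interface at the graft's lateral midpoint.
  At a 20 µm axial pitch this quantity is resolution-limited (a 1-pixel
  error is ~10% of a thin graft), unlike the six arc/cord parameters;
  tests hold it to 1.5 pixels rather than a percentage.  It is also a
  different quantity from a donor's pre-implant ultrasonic pachymetry.

Recovery, summarised per batch by the median absolute error over
QC-included eyes, is well under 1% for the six core parameters on
noiseless renders and under 3% with default speckle; individual eyes can
exceed these figures (heavy speckle over a thin slab), which is why the
batch median plus an exclusion-rate bound is the tested contract.

## Cohort simulation

`generate_cohort` works at measurement level.  Trephine diameters are
drawn from the 7.00–9.50 mm grid in 0.25 mm steps with discrete
two-sided Gaussian weights around the 9.0 mm mode (σ 0.8 left / 0.2
right), matching the reported left-skewed usage (mean ≈8.6, median and
mode 9.0).  Then:

* `PGAL = a + 1.07·trephine + ε`, ε ~ N(0, 0.43 mm), with the intercept
  chosen so the PGAL mean is the configured 9.24 mm.  These constants
  follow from the printed moments: they give SD(PGAL) ≈ 0.72 mm and a
  population Spearman correlation ≈ 0.78 with the trephine diameter.
* PCAL couples to PGAL (0.36 mm/mm + residual), ACW to PCAL, AGAL to
  PGAL via the 1.048 arc ratio, and the cords via the 1.122/1.134
  arc-to-cord ratios, with residual SDs keeping each marginal near its
  configured moments; curvature and graft thickness are independent.
  Arc ≥ cord is enforced per eye.
* The duplicate-session table perturbs every eye's parameters twice with
  per-parameter observer noise whose defaults come from the
  limits-of-agreement scale of the repeatability table
  (σ_w = SD(difference)/√2, 0.036–0.15 mm).  The printed coefficient-of-
  variation column of that table is inconsistent with its own
  limits-of-agreement column; the limits were used.

Consequences the package reports rather than targets: the emergent
stepwise adjusted R² of the PGAL model lands around 0.6–0.7 across
seeds, and the undersized fraction among large-PCAL eyes around 65–75%.

## Statistics

* **Paired comparison**: Shapiro-Wilk on the differences chooses between
  the paired t-test (p ≥ 0.05) and Wilcoxon signed-rank; identical
  sessions give p = 1 with a degenerate flag.
* **ICC**: two-way mixed-effects, absolute-agreement, single-measures —
  ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))
  with k = 2 sessions; CI by the F-distribution method with
  Satterthwaite degrees of freedom.  The repeated sessions are named
  neutrally A/B: the source table's "Observer 1/2" heads describe
  masked repeat readings by one observer.
* **CoV**: within-subject root-mean-square form,
  `100·sqrt(Σd²/2n)/grand mean`, seeded percentile bootstrap CI
  (2,000 resamples).
* **Bland-Altman**: mean difference with a t-based CI and
  mean ± 1.96·SD limits of agreement.
* **Spearman**: mid-rank correlation with the t-approximation p-value
  (scipy); a vectorised seeded bootstrap CI is provided for cohort work.
* **Regression**: OLS with intercept (statsmodels), t-based 95% CIs,
  adjusted R² = 1 − (1−R²)(n−1)/(n−p−1); rank-deficient designs raise a
  collinearity error naming the dependent columns.  Categorical
  predictors enter as factorised codes.
* **Stepwise selection**: forward entry at p < 0.05, backward
  elimination at p ≥ 0.05; the returned model is whichever of the two
  *terminal* models has the greater adjusted R² (ties toward fewer
  predictors).  Comparing only the terminals matches the selection
  behaviour the procedure is expected to show on planted-truth
  simulations (exact recovery ≈ (1−α)^k with k null candidates); scoring
  every intermediate model by adjusted R² instead would retain any null
  predictor with |t| > 1 and recover the exact truth far less often.
* All p-values are raw; no multiplicity correction is applied.

## Cohort analysis conventions

* Quantiles interpolate linearly between order statistics.
* "Undersized": PCAL strictly above the cohort 75th percentile AND
  PGAL/PCAL strictly below the cohort mean ratio (both reference lines
  strict; the fraction is reported among the large-PCAL eyes).
* `recommend_trephine` inverts the fitted linear model for the trephine
  at `target ratio × PCAL`, snaps to the 0.25 mm grid and clamps to
  [7.00, 9.50] mm.  The default target ratio 0.712 is simply the cohort
  mean; no optimal graft ratio is established clinically.
* `disc_area_increase` reports full precision and the integer truncation
  (the convention under which 8.0→9.0 mm reads as 26%).
* Report percentages are `100·count/denominator` rounded to one decimal.

## Problem sizes and determinism

Every generator and bootstrap is a pure function of (config, seed).
The test suite uses 12-eye rendered batches per noise condition, a
7-eye refraction round trip, 500-replicate bootstrap-coverage and
200-replicate selection simulations, and 10,000-draw moment checks;
`scripts/acceptance.py` uses a 109-eye cohort, 12-eye imaging batches
and a 121-image QC pass.  These sizes keep each quantity's Monte-Carlo
error well below the tolerance it is checked against.

## Known limitations

* Single-circle surfaces: no peripheral corneal flattening, so the
  printed PCAL/ACW/curvature triple cannot be reproduced simultaneously
  by one geometry (see above); no astigmatism or decentred grafts.
* Speckle is spatially white; real speckle is PSF-correlated and
  log-compressed.  Motion artefact is not modelled.
* Spurs and graft edges are inputs (operator landmarks), not detected.
* The graft-interface cleft must span at least ~3 axial pixels to be
  traceable; thinner interfaces are excluded by QC, not measured.
* The dewarp assumes a two-interface layered model with single-valued
  surfaces per column; scleral and iris refraction are folded into the
  neighbouring media.
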