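# Methods

## The measurement model

Each trial images a patch of skin over the posterior superior iliac spine
before and after five minutes of contact cooling. Two frames are captured
per shot: an optical RGB frame and a thermal frame (a temperature grid in
°C). Analysis proceeds in thermal-pixel space:

1. **Registration.** Corner points of an identification sticker visible in
   both frames give ≥3 correspondences; the 2×3 affine map minimizing the
   summed squared residuals (ordinary least squares on the stacked
   coordinates) maps optical points into the thermal frame. With exactly
   three non-collinear pairs the map is exact; collinear configurations are
   rejected.
2. **Cooling ROI.** ≥5 points clicked along the circle drawn on the skin
   are mapped through the affine and fed to a direct algebraic conic fit
   constrained to an ellipse (Halir–Flusser). The fit is deterministic,
   needs no initialization, and recovers noise-free ellipses exactly. The
   result is canonicalized to semi-axes a ≥ b and rotation θ ∈ [0, π).
3. **Control region.** The control ellipse scales each semi-axis by 1/4 and
   is displaced along the image x-axis (the "superior" direction of the
   side-lying frame; the sign is a configurable protocol convention, −x by
   default) by the control ellipse's full long-axis width (2·a/4) plus the
   cooling semi-major axis a, i.e. 1.5·a in total. If any control pixel
   leaves the frame or lands on an invalid region (sticker, clothing), the
   center moves to the nearest valid position found by an exhaustive radial
   sweep at 1-px steps, ties broken by smaller polar angle — a deterministic
   automation of a manual "nearest appropriate location" rule. The offset
   factor and direction are single config constants, because the verbal
   protocol admits alternative readings.
4. **Extraction.** A pixel belongs to an ellipse iff its center satisfies
   the rotated-ellipse inequality ≤ 1 (no partial-area weighting: this keeps
   the statistic oracle-checkable). The region statistic is the median, with
   even counts averaged between the central order statistics. Medians are
   invariant to pixel permutation and shift exactly with additive offsets,
   so the ROI−control difference cancels any global (camera-level) offset.

## Statistical layer

One measurement row per image × region (median temperature, factor levels,
melanin). Two outcomes mirror the study design: the **absolute** ROI median,
and the **differential** ROI−control median difference (clinically relevant;
insensitive to global offsets). Models are linear mixed-effects with a
per-subject random intercept, fitted by REML via `statsmodels.MixedLM`.
Reference levels: camera E8-XT, distance 35 cm, phase baseline, posture
knees-stacked, lighting room.

Denominator degrees of freedom use Satterthwaite's approximation, computed
from the closed-form REML likelihood of the random-intercept model: for a
coefficient contrast c, df = 2·v² / (gᵀA g), where v = cᵀ(XᵀV⁻¹X)⁻¹c, g its
gradient in the variance components (σ², σ_b²) by central differences, and
A the inverse negative numerical Hessian of the REML log-likelihood. On
shared fixtures this reproduces lme4/lmerTest coefficients to ~1e-7 and df
to ~0.1% (cross-checked in the test suite through Rscript). When the
intercept variance sits on the boundary (singular fit) the implementation
falls back to residual degrees of freedom, n − rank(X), and says so in the
result's notes; coefficients and standard errors are unaffected.

The skin-tone model adds converted melanin and its interaction with
cooling. By default the covariate enters **uncentered**, matching the
convention in which the cooling main effect is reported at melanin zero
(an lme4 fit with a raw covariate); centering at the cohort mean is an
option (`melanin_centered=True`) and changes only the phase main effect, by
exactly β_interaction × mean melanin.

Effect sizes: Cohen's d bands at 0.2/0.5/0.8. For paired comparisons both
conventions are reported — mean difference over the SD of differences, and
over the pooled SD of the two sets — because published paired d values are
not always derivable from one convention.

## Melanin colorimetry

Device scales differ: the SkinColorCatch index x is mapped to the ColorMeter
DSM-II scale by y = exp((x + 623.18)/334.81) (fitted across PANTONE skin-tone
swatches; the fitted constants are used as given, not re-estimated). The
skin-tone categories (modified Eumelanin Human Skin Colour Scale) are
half-open intervals on the converted scale with left-closed cutoffs at 25,
37.5, 50, 75, 100. Published cohort summaries of "melanin index" are
ambiguous about which scale they report; both scales are carried through the
pipeline, and the statistical covariate uses the converted scale, whose
25-unit spacing underlies the per-category arithmetic (β × 25 per category,
β × 75 across the Intermediate Low → Intermediate High span).

## The synthetic-study generator

The generator emulates the study conditions so that pipeline estimates
become parameter-recovery checks. Cohort: 35 subjects; baseline site
temperature ~ N(30.8, 0.9²) °C (the 0.9 acting as the subject random
intercept); converted melanin ~ truncated normal (55.94, 13.54²) on
[25, 100), which reproduces the reported category proportions (a cohort
concentrated at Intermediate Mid); raw melanin follows by inverting the
conversion. Each subject is imaged under the full factorial — 2 cameras
(E8-XT 320×240, ONE Pro 160×120) × 2 phases × 2 lighting × 2 distances × 3
postures = 48 images — with the marked circle scaled 0.7× at 50 cm, and a
known affine (scale 0.5, small rotation and shift) linking the optical and
thermal frames. Boundary points are exact ellipse points plus 0.3 px of
optical-pixel click jitter.

Thermal frames are additive fields: surrounding-skin level, whole-frame
terms (camera offset, distance, posture/lighting, cooled-phase shift,
per-image drift), a site plateau carrying the ROI−control baseline gap,
local per-region fluctuations, the cooling depression, and per-pixel noise.
The depression is a raised-cosine profile that is **flat over the entire
drawn circle** (plateau at 1.02× the ROI) and tapers to zero at 1.15×,
safely inside the control region's inner edge at 1.25·a. A plateau covering
the whole ROI is what makes the ROI median equal the nominal depth plus a
symmetric noise term: any taper inside the ROI would place the median on the
taper shoulder and bias it warm by ≈0.57 σ_pixel.

### Calibration

Fixed-effect defaults are the study's printed values, with two derived
quantities the printed values jointly imply:

| parameter | default | units | meaning |
|---|---|---|---|
| cooling depth, E8-XT | 4.19 | °C | marginal (distance-averaged) ROI cooling |
| cooling × camera (absolute) | 1.89 | °C | ONE Pro records this much less cooling |
| camera offset, ONE Pro | −2.43 | °C | global baseline offset |
| cooling × camera (differential) | 1.04 | °C | interaction on ROI−control |
| distance (50 vs 35 cm) | −0.11 | °C | whole-frame, baseline |
| distance × cooling | +0.20 | °C | whole-frame, cooled phase |
| posture, lighting | 0 | °C | null effects |
| melanin × cooling | −0.013 | °C/unit | per converted melanin unit, centered at the cohort mean |
| baseline ROI−control gap | −0.3 | °C | site runs cooler than surround |
| control cooled-phase shift, E8-XT | −0.34 | °C | see below |

Two bookkeeping points matter. First, models that omit a balanced factor
estimate the **marginal** contrast: with a distance×cooling interaction of
+0.20 in the data, the camera model's phase coefficient is the
distance-average, so the configured depths are defined as those marginal
values and the rendered 35-cm depression is deeper by 0.10 °C. Second, the
absolute interaction (1.89) and differential interaction (1.04) can only
coexist if the control region itself responds to the cooled phase
differently per camera; the shifts −0.34 °C (E8-XT) and +0.51 °C (ONE Pro)
are the unique pair consistent with both interactions, an E8-XT differential
cooling of −3.95 °C, and a pooled control-region change of ≈ +0.2 °C. A
"perfect re-acclimation" control (change ≡ 0) cannot reproduce the two
printed interactions simultaneously.

### Dispersion defaults

Values not fixed by the study were chosen once, on physical plausibility,
and frozen: subject-level SD of the baseline gap 0.15 °C (the control sits
a few cm from the ROI on the same tissue), per-image whole-frame drift
0.25 °C (session/ambient variation; cancels in the differential), per-image
per-region local fluctuation 0.20 °C (perfusion variation; the dominant
residual of the differential outcome), pixel noise 0.15 °C (E8-XT) and
0.30 °C (ONE Pro), reflecting industrial- vs consumer-grade sensors.
Between-subject variance in cooling response beyond the melanin term is
deliberately **zero**: the prescribed analysis model is a random-intercept
(not random-slope) LMM, and a generator with unmodeled subject-level slope
variance would make that model's standard errors anticonservative — the
coverage checks would then measure a model-misspecification artifact rather
than the pipeline's correctness. Consequently the generator's
between-subject SDs of the change scores are smaller than the published
ones (e.g. ±0.6 °C for ROI change), which fold in sources the generator
does not separate. This is a known, accepted mismatch.

## What passing tests do and do not show

The generator shares the pipeline's own geometric conventions (true ROIs
are ellipses; fiducials are exact up to click jitter; skin is flat and
perpendicular to the camera). Recovery therefore validates the
implementation — registration algebra, ROI geometry, median extraction,
model fitting and inference — under the study's design, not the physics of
real thermograms: body curvature, angle-of-incidence and emissivity
artifacts, lens distortion, motion, and physiological heterogeneity in
cooling response are all outside the generative model.

## Problem sizes and numerical choices

- Full-scale validation: one end-to-end study of 35 subjects / 1680 images
  (≈15 s), used for the two-standard-error recovery checks and by
  `scripts/acceptance.py`.
- Replicate coverage: 20 measurement-level replicates of the default
  configuration (the image stage bypassed; identical effect structure and
  noise components, with pixel-median noise entering through its
  large-sample standard error 1.2533·σ/√n). Every nonzero coefficient's 95%
  CI covers its generative value in ≥90% of replicates; posture/lighting
  are non-significant in ≥90%.
- Type-I control: 400 all-null studies at 20 subjects; fixed-effect
  rejection rates at the 5% level fall within 5% ± 2%.
- All randomness descends from one root seed through named substreams
  (cohort / per-image / per-subject measurement), so any image or stage is
  reproducible in isolation and a fixed seed reproduces a study
  bit-for-bit.
- Tolerances: affine and ellipse recovery are exact to ≤1e-6 on noise-free
  input; Satterthwaite finite-difference steps are relative (1e-4) with
  boundary clamping; rank-deficient designs and degenerate conics are
  rejected rather than silently regularized.

## Known limitations

- The control-relocation rule (radial sweep, angle tie-break) is one
  deterministic reading of a manual protocol; a different distance metric
  or tie-break could pick a different (equally valid) site.
- Satterthwaite df is exact only as the REML Hessian is; at near-singular
  fits the residual-df fallback can make p-values slightly liberal. 
  Coefficients and standard errors are the primary surface.
- The published paired-comparison d values are not exactly recoverable from
  rounded summary tables under either d convention; both are reported,
  neither asserted.
- No multiple-testing correction is applied, matching the source analysis.
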