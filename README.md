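# skintherm

Analysis pipeline for infrared-thermography studies of induced skin cooling,
built around the question of whether thermal imaging detects early
pressure-injury signals equitably across skin tones, cameras, and clinical
imaging conditions.

Thermography is a candidate tool for detecting pressure injuries before
visible erythema appears — a detection gap that disproportionately affects
people with dark skin tones, in whom erythema is hard to see. A validation
study of this kind cools a spot of skin over the posterior superior iliac
spine (PSIS) with a cold stone, images it with two thermal cameras (an
industrial FLIR E8-XT and a consumer FLIR ONE Pro) under varied lighting,
distance and posture, and asks how large the measured temperature change is,
how it differs between cameras and conditions, and how it varies with skin
melanin content.

`skintherm` implements that workflow end to end:

- **Registration** — least-squares affine mapping of optical to thermal
  pixel coordinates from ≥3 fiducial (sticker-corner) correspondences.
- **Regions of interest** — direct algebraic best-fit ellipse through ≥5
  boundary points marking the drawn circle; an automatically placed control
  ellipse with semi-axes a/4, b/4, displaced 1.5·a superior along the image
  x-axis, relocated deterministically to the nearest valid position when it
  collides with a sticker or clothing; exact pixel-center membership and
  median-temperature extraction.
- **Colorimetry** — conversion of SkinColorCatch melanin indices to the
  ColorMeter DSM-II scale, `y = exp((x + 623.18)/334.81)`, and assignment of
  modified Eumelanin Human Skin Colour Scale categories (cutoffs 25, 37.5,
  50, 75, 100).
- **Statistics** — within-subject averaging, one-sample and paired t-tests
  with Cohen's d (0.2/0.5/0.8 bands), and random-intercept linear
  mixed-effects models fitted by REML, with Satterthwaite denominator
  degrees of freedom, on either the absolute ROI temperature or the
  clinically relevant ROI−control difference:

  ```
  y_ij = β₀ + β₁·cooled_ij + β₂·camera_ij + β₃·(cooled×camera)_ij + … + u_i + ε_ij
  u_i ~ N(0, σ_b²),   ε_ij ~ N(0, σ²)
  ```

- **Synthetic studies** — a calibrated generator producing a full cohort
  (melanin, baseline temperature) and every optical/thermal image pair of
  the factorial design (2 cameras × 2 phases × 2 lighting × 2 distances × 3
  postures = 48 images/subject), with known ground-truth effects so every
  estimate the pipeline produces can be validated by parameter recovery.

## Worked example

```python
from skintherm import (GenerativeConfig, simulate_measurements, fit_lmm,
                       skin_tone_report)

cfg = GenerativeConfig(n_subjects=35, rng_seed=7)
meas = simulate_measurements(cfg)
res = fit_lmm(meas, outcome="differential",
              fixed_terms=("phase", "camera", "phase:camera"))
print(res.summary())
```

```
Random-intercept LMM (differential outcome, REML)
obs = 1680, subjects = 35
sigma^2 (residual) = 0.0911, sigma^2 (subject) = 0.0306
df method: satterthwaite

term                              estimate       se       df          p                95% CI
Intercept                          -0.3260   0.0331     46.9   5.08e-13   [-0.393, -0.260]
phase[cooled]                      -3.9445   0.0208   1642.0          0   [-3.985, -3.904]
camera[ONEPro]                      0.0111   0.0208   1642.0      0.594   [-0.030, +0.052]
phase[cooled]:camera[ONEPro]        1.0212   0.0295   1642.0  4.38e-198   [+0.963, +1.079]
```

Read: at baseline the cooled-site ellipse runs ≈0.33 °C cooler than its
control region; cooling deepens that difference by ≈3.94 °C on the
industrial camera; there is no camera difference at baseline (p = 0.59),
but the consumer camera registers ≈1.02 °C less of the cooling change.

The melanin interaction, fitted on the industrial-camera subset and
translated onto the skin-tone scale (categories are 25 converted units
apart):

```python
mel = fit_lmm(meas[meas.camera == "E8XT"], outcome="differential",
              fixed_terms=("phase", "melanin", "phase:melanin"))
print(skin_tone_report(mel))
```

```
{'per_unit_C': -0.01336, 'per_category_C': -0.33394, 'across_scale_C': -1.00182,
 'p': 4.6e-20}
```

i.e. each additional converted melanin unit deepens the measured cooling by
0.013 °C — about 0.33 °C per skin-tone category, or 1.0 °C between the
Intermediate Low and Intermediate High categories.

The same analysis runs from the shell:

```bash
skintherm all --seed 7 --outdir out/   # simulate → extract → analyze → report
```

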