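# Methods

## Model and assumptions

Observed signal in the primary (fluorophore) channel is modeled as an
additive mixture of true fluorophore signal and autofluorescence (AF):

    G_obs = G_fluo + G_af

The method assumes a **single dominant AF component** with a fixed emission
spectrum, so AF contributions to the primary channel and to a red-shifted
predictor channel A (same excitation) are linearly proportional per pixel:

    G_af = m · A_obs + c                        (two-channel)

The intercept `c` absorbs constant background-offset differences between
channels. With a co-expressed red fluorophore, A additionally carries
bleedthrough proportional to the dedicated red channel R, so

    G_af = m1 · A_obs + m2 · R_obs + c          (three-channel)

Because red signal inflates A without matching primary-channel signal, the
fitted `m2` is negative: in the generator's parameterization,
`m2 = −m_true · rfp_bleed_true`.

Coefficients are estimated by ordinary least squares on pixels pooled from
calibration images in which all primary-channel signal is AF (unlabeled
samples for two-channel, red-only samples for three-channel). Calibration and
experimental images must be acquired under identical settings; the loader
logs a warning when shapes or bit depths differ.

### Fluorophore spillover into the predictor channel

A small fraction `s` of fluorophore emission leaks into A
(`A_obs = A_af + s·G_fluo`). Subtracting `AF* = m·A + c` then leaves
`(1 − m·s)·G_fluo`: spillover only rescales the corrected signal, so it can
be ignored for normalized comparisons or compensated by dividing by
`(1 − m·s)` (which requires `m·s < 1`).

`estimate_spillover` uses a two-pass scheme: correct spillover-calibration
samples with the base model, giving per pixel `g1 = (1 − m·s)·G_fluo +
noise`, then regress the filtered predictor on `g1`; the slope is
`β = s/(1 − m·s)`, solved as `s = β/(1 + β·m)`. This is unbiased only if the
fluorophore distribution varies **independently of the AF field within the
ROI**. In practice that means: use strongly expressing samples with spatial
fluorophore structure (membranes, nuclei) and draw the ROI over the sample
interior only — including background creates a sample/background contrast
common to both AF and fluorophore that biases `β` upward. Estimates implying
negative `s` (including fluorophore-free input, where the regressor is pure
noise) are truncated to 0 with a warning.

## Estimation details

- **Gaussian pre-filter.** Pooled pixels are smoothed (sigma = `radius`
  pixels, reflection at image edges to avoid dark-border bias) before
  regression; raw pixel values correlate poorly between channels because
  independent shot noise in each channel dilutes the fit. The practical
  radius range is 1–2 px; the default is 2 px, favoring stability on noisy
  cameras. Radius 0 is the identity.
- **Correction-time filtering.** At correction the predictor channel(s) are
  smoothed at the model's stored radius; the primary channel never is.
  Subtracting an inferred image combines pixel noise from multiple channels;
  smoothing predictors suppresses that amplification while preserving
  primary-channel resolution. The unfiltered behavior is available
  (`filter_predictors=False` / `--no-filter-predictors`).
- **OLS solver.** `numpy.linalg.lstsq` (orthogonal decomposition), not
  explicit normal-equation inversion; the minimizer is unique under the
  full-rank preconditions that the fit functions enforce (zero-variance and
  collinear predictors are rejected with named errors).
- **Pooling.** All ROI pixels are used (no subsampling); a single global
  intercept is shared across samples. Per-sample slopes/R² are reported as
  diagnostics only, never applied. Pixels at the detector maximum are
  excluded with a logged count (saturation breaks linearity). Pooling warns
  below three calibration samples. A `low_intensity_fraction` diagnostic
  reports whether the pool anchors the fit at background intensities, since
  ROIs are recommended to include some sample-free background.
- **Whole-sample variant.** The same regressions can be fitted on per-sample
  ROI means (one observation per sample, unfiltered). Under the shared linear
  model these estimate the same coefficients and may be applied per pixel.
- **Signed output.** Negative corrected values are never clipped — a
  negative fraction above ~5% of ROI pixels is the standard symptom of
  wrong-mode calibration (e.g. two-channel correction of a red-expressing
  sample) and is surfaced by `overcorrection_report`. Zero-clipping exists
  only as a display-export option.
- **Exactness.** Without spillover, `corrected` is exactly
  `primary − AF*` pixel-wise in double precision; no processing touches the
  primary channel. (The re-summed form `corrected + AF*` matches the input
  to within one floating-point ulp, as addition re-rounds.)

## Quantification

- ROI means are arithmetic means over nonempty boolean masks; the
  coefficient of variation uses the n−1 standard deviation.
- Cross-membrane profiles sample the image along local normals of a
  user-supplied sub-pixel contour at equal arc-length steps (default 1 px),
  50 samples spanning ±25 px by default, via cubic-spline (bicubic)
  interpolation. Pixel centers sit at integer coordinates, origin top-left,
  x rightwards, y downwards; outward normals follow contour winding, and
  distance is negative outside / positive inside, membrane at 0. Linescans
  leaving the frame are dropped with a count.
- Profile averaging over a partial arc (e.g. "posterior-most 30% of the
  circumference") selects a contiguous arc-length fraction centered on a
  user-supplied anchor point; no axis-detection heuristic is attempted.

## Synthetic scenes

`synthetic` renders an elliptical "embryo" (default 140×200 image,
semi-axes 50×80 px) with:

- **AF field** — smoothed white noise (correlation length
  `af_texture_scale`, default 8 px; relative amplitude 0.2), rescaled so the
  embryo mean equals the sample's drawn AF level; levels are log-uniform
  over a 2-fold inter-sample range (`af_base_level` 200, `af_fold_range` 2),
  matching the variability seen in real embryos. AF falls off smoothly at
  the boundary (`af_edge_softening`, default 3 px, emulating optical blur);
  optional central void emulates AF exclusion by the pronuclei/spindle.
- **Channel identities** (held exactly, pre-noise, in `truth`):
  `G = G_fluo + m_true·A_af + c_true`,
  `A = A_af + s_true·G_fluo + rfp_bleed_true·R_rfp`, `R = R_rfp`.
  Defaults `m_true = 1.8`, `c_true = 100` (AF brighter in the green band
  than in the red-shifted one; `c` a channel background offset),
  `rfp_bleed_true = 0.05`.
- **Fluorophore layouts** — none, uniform cytoplasm, membrane band (Gaussian
  cross-section centered on the ellipse boundary, so profile extraction has
  a known peak at distance 0), or cytoplasm with a nuclear void.
- **Noise** — additive Gaussian (sd 5) plus optional signal-proportional
  variance (`noise_poisson_gain`, off by default).
- An optional second, punctate AF source with its own inter-channel slope
  exercises the known failure mode (below); it is not part of default
  scenes.

All randomness flows from one explicit seed; cohort scene *i* derives its
stream from `(seed, i)`, so cohorts are bit-reproducible and independent of
cohort size.

What the generator does **not** emulate: optics (PSF), photobleaching,
motion between sequentially captured channels, realistic organelle
morphology, detector artifacts beyond the noise model. Passing tests
demonstrate correctness of the estimators under the stated linear model and
noise — not robustness to violations of it beyond those explicitly
simulated (red bleedthrough, spillover, a second AF source).

### Problem sizes used in tests

Default scenes carry ~12.6k embryo pixels (~21k ROI pixels with the 15 px
background margin). Calibration fits pool 5–10 scenes (~1–2·10⁵ pixels);
cohort-level checks use 10–20 scenes per condition — enough that Monte-Carlo
error sits well inside the asserted tolerances.

## Known limitations

- A single dominant AF component is assumed. With multiple independently
  varying AF sources the inter-channel correlation degrades (the generator's
  granule option reproduces this: calibration R² drops and residuals become
  structured) and granule-like AF is over-subtracted.
- Eggshell-type fluorescence behaves like a red fluorophore with strong
  bleedthrough and is handled by the three-channel path with an
  eggshell-bearing calibration set; eggshell and a red fluorophore cannot be
  compensated simultaneously, since they occupy the same predictor.
- Correction combines noise from multiple channels; no denoising of the
  corrected output is attempted.
- Channels must be co-registered; no registration, drift correction, or
  3-D handling beyond plane-by-plane application is provided.
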