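# saibr

Spectral autofluorescence correction for multi-channel fluorescence
microscopy, by inter-channel regression — a scriptable library and CLI
(`afcorrect`).

## The problem

When imaging dim fluorophores (endogenously tagged GFP/mNeonGreen fusions in
*C. elegans* embryos, yeast, oocytes, ...), endogenous autofluorescence (AF)
can account for much of the signal in the fluorophore channel, and it varies
both across a sample and ~2-fold between samples. Subtracting one average AF
value therefore fails; what is needed is a per-pixel, per-sample estimate of
AF in the fluorophore channel.

AF has a broad emission spectrum, so it is also captured in a red-shifted
"predictor" channel (same excitation, red-shifted emission filter) where the
fluorophore contributes almost nothing. Treating AF as a single spectral
component, its contributions to the two channels are linearly proportional:

```
G_obs = G_gfp + G_af,        G_af = m · A_obs + c
```

`m` and `c` are fitted by ordinary least squares on (Gaussian-filtered)
pixels pooled from unlabeled calibration samples, in which all
primary-channel signal is AF. Correction then subtracts the inferred AF image
`AF* = m·A + c` pixel-wise from the primary channel. With a co-expressed red
fluorophore, red emission bleeds into the predictor channel; a three-channel
model fitted on red-only samples compensates it:

```
G_af = m1 · A_obs + m2 · R_obs + c        (m2 < 0: red signal in A mimics AF)
```

A small proportional spillover `s` of fluorophore emission into the predictor
channel only rescales the corrected signal by `(1 − m·s)`; it can be
estimated from strongly expressing samples and compensated.

The package also ships the downstream quantification used with such data
(ROI means, coefficients of variation, averaged cross-membrane linescan
profiles) and a synthetic-scene generator with exact per-pixel ground truth
(latent AF / fluorophore / red components, 2-fold inter-sample AF variation,
camera-like noise) so the whole pipeline is testable end-to-end without real
data.

## Worked example

Calibrate on ten simulated unlabeled samples, correct a labeled cohort, and
compare against the scalar mean-AF-subtraction baseline:

```python
import numpy as np
from saibr import (SceneParams, make_cohort, build_pixel_pool,
                   fit_two_channel, correct, coefficient_of_variation,
                   mean_af_reference, mean_af_subtract)

cal = make_cohort(SceneParams(seed=7), 10)                # unlabeled scenes
pool = build_pixel_pool([s.stack for s in cal], radius=2.0)
model = fit_two_channel(pool)
print(f"fitted: m={model.m:.4f}  c={model.c:.3f}  R^2={model.r_squared:.5f}")

labeled = make_cohort(SceneParams(seed=99, gfp_layout="uniform_cytoplasm",
                                  gfp_amplitude=150.0), 10)
means = np.array([correct(model, s.stack).roi_mean_corrected for s in labeled])
print(f"cohort mean {means.mean():.2f}, c.o.v. {coefficient_of_variation(means):.4f}")
baseline = mean_af_subtract([s.stack for s in labeled],
                            mean_af_reference([s.stack for s in cal]))
print(f"mean-AF-subtraction c.o.v. {coefficient_of_variation(baseline):.4f}")
```

Output:

```
fitted: m=1.7997  c=100.060  R^2=0.99994
cohort mean 97.08, c.o.v. 0.0006
mean-AF-subtraction c.o.v. 0.5652
```

The fit recovers the generating inter-channel slope (1.8) and offset (100)
almost exactly. The corrected cohort mean (97.08) matches the ground-truth
fluorophore mean (97.07), and because each sample's AF is inferred from its
own predictor channel, the spread across samples (c.o.v. 0.0006) is orders of
magnitude below the baseline that subtracts one cohort-average AF scalar
(0.5652) and is blind to the 2-fold inter-sample AF variation.

The same workflow from a shell:

```sh
afcorrect simulate --preset unlabeled --n 10 --seed 7 --out cal/
afcorrect calibrate --unlabeled cal/ --mode 2ch --gaussian-radius 2.0 --out model.json
afcorrect simulate --preset gfp --n 10 --seed 99 --out gfp/
afcorrect correct --model model.json --input gfp/ --out corrected/
afcorrect quantify --input corrected/ --roi-dir gfp/ --report report.csv
```

## Documentation

See `docs/methods.md` for the model, estimators, parameter defaults, the
synthetic generator's scope, numerical choices, and known limitations.
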