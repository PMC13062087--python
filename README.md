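# respsense

Respiration-phase-resolved analysis of perception and neural dynamics:
a tested, reusable pipeline for experiments that ask how the breathing
cycle modulates detection behaviour, oscillatory power, and directed
cortical network communication.

The package is aimed at researchers analysing cued near-threshold
detection experiments with simultaneous respiration (belt), pupillometry,
and ROI-level neural time series (e.g. source-localised MEG). Because such
datasets are typically access-restricted, the package ships a synthetic
session generator with known ground truth, so every stage of the analysis
is verified by parameter recovery rather than by eyeballing.

## What it computes

- **Respiratory phase** — traces are z-scored, sigh artefacts (|z| > 2.5)
  clipped by interpolation, inspiratory peaks / expiratory troughs
  detected with prominence 1, and phase interpolated linearly per
  half-cycle: trough = -pi (start of inspiration), peak inspiration = 0,
  expiration spans 0..pi.
- **Adaptive staircase and psychometrics** — a QUEST staircase holding
  performance at a hit-rate criterion mu_HR = 0.60; cumulative-Gaussian
  psychometric fits Psi(x) = gamma + (1 - gamma - lambda) Phi((x - m)/sigma)
  with gamma = 1/3; and a moving-window refit across the respiratory cycle
  (step pi/30, window +-pi/10, 60 windows) yielding a z-scored,
  phase-resolved threshold profile.
- **Circular statistics** — Rayleigh and Hodges-Ajne tests, circular-linear
  correlation, paired circular-difference permutation test, and
  sine/cosine phase regression y ~ b0 + b_sin sin(theta) + b_cos cos(theta)
  with amplitude sqrt(b_sin^2 + b_cos^2) and preferred phase
  atan2(b_sin, b_cos).
- **Spectra** — DPSS multitaper power (1-40 Hz, 2 Hz smoothing) on the
  prestimulus [-1600, 0] ms window, first-order-derivative spectral
  whitening, head-motion GLM cleanup (36 regressors), and power binned
  into 30 moving respiration-phase windows.
- **Directed connectivity** — nonparametric blockwise Granger causality
  between 3-principal-component ROI blocks via Wilson's spectral matrix
  factorisation S(f) = H(f) Sigma H(f)*, the directed asymmetry index

      DAI(f) = (mGC_{A->B}(f) - mGC_{B->A}(f)) / (mGC_{A->B}(f) + mGC_{B->A}(f)),

  and the whole chain repeated per respiration-phase bin (30 bins) with a
  first-level sine/cosine regression of GC on phase.
- **Inference** — cluster-based permutation statistics (point-wise t at
  p = 0.05, sum-of-|t| cluster statistic, 5000 label permutations, 97.5th
  percentile), Benjamini-Hochberg FDR, Gaussian-copula mutual-information
  model comparison for single-trial detection, and cluster-corrected
  brain-behaviour correlations.

## Worked example

Simulate a full session (720 trials, 6 runs) and run every analysis stage,
then validate the estimates against the generator's ground truth:

```bash
respsense run --out demo_run --seed 3
```

which prints the recovery report:

```
                  check  truth   estimate   tol  passed
     breathing_rate_bpm   15.0  14.934890  1.00    True
               hit_rate    0.6   0.618182  0.03    True
threshold_min_phase_deg  -60.0 -68.183601 30.00    True
         power_depth_V1    0.2   0.205218  0.05    True
     power_phase_V1_deg  -60.0 -60.367903 20.00    True
        gc_mod_dai_sign    1.0   0.832461  0.20    True
```

Reading it: the breathing rate extracted from the clipped belt trace
recovers the generator's 15 breaths/min; the staircase held the hit rate
near its 0.60 criterion; the phase-resolved psychometric refit places the
threshold minimum at -68 degrees, within tolerance of the generator's
highest-sensitivity phase (-60 degrees, late inspiration); phase-binned
alpha power recovers the 0.2 modulation depth and its -60 degree phase;
and the DAI of the phase-modulation of Granger causality is strongly
positive at the coupled band, naming the true INS -> TPJ direction. The
run directory holds the per-stage artefacts (`trials.tsv`,
`respiration.tsv` + JSON sidecar, `roi_epochs.h5`,
`threshold_profile.tsv`, `power_phase_regression.tsv`,
`gc_phase_regression.tsv`, `recovery_report.tsv`, `manifest.json`).

The same stages are available individually (`respsense simulate`,
`physio`, `psychometrics`, `spectra`, `gc`, `validate`), and everything is
importable as a library:

```python
from respsense.physio import normalize_and_clip, detect_extrema, interpolate_phase
from respsense.connectivity import csd_multitaper, wilson_factorize, block_gc, dai
```

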