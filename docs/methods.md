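# Methods

`respsense` implements a respiration-phase-resolved analysis chain for
cued near-threshold detection experiments with simultaneous physiological
and ROI-level neural recordings, together with a generative model of such
sessions that makes every estimator testable by parameter recovery. This
note documents the models, the conventions, the numerical choices, and
what the synthetic benchmarks do and do not establish.

## Respiratory phase

Respiration belt traces are z-scored and clipped: contiguous runs with
|z| > 2.5 (sighs, artefacts) are replaced by linear interpolation between
the flanking retained samples. Because interpolation changes the mean and
variance, the z-score/clip pass is iterated to a fixed point, so the
operation is idempotent; runs touching a recording edge are filled with
the nearest retained value. Inspiratory peaks and expiratory troughs are
detected with a minimum prominence of 1 z-unit (troughs on the negated
trace), and the merged sequence is forced to alternate by keeping the more
extreme of two consecutive same-type extrema.

Phase is linearly interpolated per half-cycle: trough to peak spans
-pi..0, peak to trough spans 0..pi. Troughs (start of inspiration) carry
-pi, peak inspiration carries 0, so "inspiration" is the (-pi, 0)
half-cycle and the realised range is [-pi, pi). Samples before the first
and after the last extremum have undefined phase (NaN); events there are
excluded and logged rather than extrapolated. Breathing rate is 60 / mean
inter-peak interval.

This piecewise-linear convention treats each half-cycle as an equal
angular span regardless of its duration, which is exactly what trial
sorting by "phase at target onset" requires; it is not an analytic-signal
phase and should not be differentiated.

## Pupil

Area traces are converted to diameter (d = 2 sqrt(area/pi), linearising
the size measure). Blinks are detected as dropouts below 30% of the median
diameter plus a velocity criterion (first difference beyond 6 robust
z-units), padded by 100 ms on each side, and linearly interpolated; a
second, relaxed artefact pass interpolates |z| > 6. A canonical blink
response (double-gamma kernel convolved with the blink onset train, kernel
timescale fitted coarsely per recording) can be regressed out. The trace
is then band-passed 0.01-10 Hz (2nd-order Butterworth, forward-reverse)
and robust z-scored, (x - median) / (1.4826 MAD), so the output has median
0 and robust scale 1 by construction.

## Staircase and psychometrics

The psychometric function is a cumulative Gaussian,
Psi(x) = gamma + (1 - gamma - lambda) Phi((x - m)/sigma), with the guess
rate fixed at 1/3 for the three-response single-interval task and contrast
dimensionless in [0, 1].

QUEST maintains a grid posterior over log10 contrast. Its internal
psychometric model (slope beta = 3.5 per log10 unit, lapse delta = 0.01)
is anchored so that a stimulus placed exactly at the tracked threshold T
yields the criterion probability (0.60); each trial is placed at the
posterior mean of T. At the fixed point of this rule the posterior
concentrates where the model's prediction at the tested contrast equals
the observer's true hit probability, so the empirical hit rate converges
to the criterion even under slope mismatch between model and observer.
The sequential update is validated against a brute-force
product-of-likelihoods posterior (agreement < 1e-10 over 720 trials), and
a stationary simulated observer lands within 0.03 of the criterion over
post-burn-in trials.

The overall psychometric fit is a grid MAP over (m, sigma, lambda) with
gamma fixed, a Beta(1, 20)-shaped prior on the lapse, and marginal 95%
credible intervals read off the grid posterior. The threshold is the
contrast at the unscaled-sigmoid midpoint. The phase-resolved refit moves
a window of half-width pi/10 in steps of pi/30 across the cycle
(60 windows; each trial contributes to 6), refits with Gaussian priors on
m and sigma centred on the overall estimates (SD = 2x the overall marginal
posterior SD — weakly informative around the global fit, since no tighter
prescription exists), requires at least 10 trials per window, and z-scores
the threshold profile across defined windows. Group inference is a
per-window two-sided one-sample t-test of the z-scored thresholds against
zero with Benjamini-Hochberg FDR across windows.

## Circular statistics

- Circular-linear correlation: rho from the pairwise correlations of x
  with sin/cos of the angle; p from the chi^2_2 approximation of
  n rho^2.
- Rayleigh: z = n Rbar^2 with the standard finite-n p correction.
- Hodges-Ajne: m = minimum count in a closed half-circle; exact p for
  n <= 50 (p = 1 at m = n/2, the weakest clustering), normal approximation
  above. The exact test is conservative because its p-values are discrete;
  calibration tests compare against the attainable level.
- Phase regression: OLS on [1, sin, cos]; amplitude and preferred phase
  are the polar form of the sine/cosine weights.
- Paired circular difference: sign-flip permutation (10^4 flips; exact
  enumeration below n = 5) of d = wrap(a - b) with statistic |mean sin d|,
  the component of the mean resultant orthogonal to the null direction.
- Binning: 30 equal right-closed bins partitioning (-pi, pi] (ties broken
  deterministically toward the bin ending at the edge), or moving windows
  of half-width pi/10 at 30 (power) / 60 (thresholds) centres.

## Spectra

Epochs span [-1.85, 0.75] s around target onset at 300 Hz (anti-aliased
polyphase resampling); all spectral estimates use the prestimulus
[-1600, 0] ms window. Head-motion cleanup regresses out the 6 rigid-body
signals and their derivatives expanded to polynomial orders 1-3
(36 regressors) plus a 3rd-order polynomial drift basis.

The aperiodic component is suppressed by first-order derivative whitening;
the first-difference gain 2 sin(pi f / fs) ~ f inverts a 1/f amplitude
(1/f^2 power) background over the analysis band, shortening each epoch by
one sample. Power spectra are DPSS multitaper estimates (mne), 1-40 Hz,
with 2 Hz one-sided smoothing; the taper count is floor(2 NW) - 1 with
NW = smoothing x window length. Phase-binned power averages per-trial
spectra within moving phase windows; a cosine (phase regression) fit to
the binned profile recovers generator modulation depth 0.2 within 0.05 and
modulation phase within 20 degrees at 600 trials.

## Directed connectivity

For each ROI pair, the first three principal components per ROI (computed
across concatenated trials, so one spatial basis per ROI) form a
6-channel block. The cross-spectral density is a trial- and taper-averaged
DPSS estimate on the uniform FFT grid from 0 to Nyquist (2 Hz smoothing,
0-150 Hz reported). Wilson's spectral matrix factorisation
S(f) = H(f) Sigma H(f)* is initialised from the Cholesky factor of the
frequency-averaged spectrum and iterated with the causal-projection
update; S is diagonally loaded by 1e-8 x mean power. Convergence is
declared when the relative reconstruction residual falls below 1e-8 or
when the iteration reaches its fixed point — on estimated CSDs the
circular-lag truncation of the finite grid floors the residual around
1e-5; residuals above 1e-3 raise an error. On analytic VAR spectra the
residual reaches < 1e-6 and the innovation covariance is recovered within
5%.

Blockwise Granger causality follows Geweke's spectral form,
f_{A->B}(f) = ln det S_BB / det(S_BB - H_BA Sigma_{A|B} H_BA*), with the
conditional innovation covariance partialled on the target block;
negative numerical excursions are clipped at zero. The estimate matches
parametric GC computed from true VAR coefficients within 10% at the
spectral peak. The DAI, (f_AB - f_BA)/(f_AB + f_BA), is antisymmetric and
bounded in [-1, 1] by construction; frequencies with denominator below a
floor are reported missing.

Phase-resolved GC repeats the full CSD -> factorisation -> block-GC chain
per non-overlapping phase bin (30 bins, minimum 15 trials per bin in the
pipeline; the ROI component basis is computed once on all trials). The
first-level regression predicts GC per frequency and direction from
[1, sin, cos] of the bin centre; because the raw sine/cosine weights are
signed, the DAI is applied to the two directions' nonnegative modulation
magnitudes sqrt(b_sin^2 + b_cos^2). Regression statistics are restricted
to 0-40 Hz.

Two properties of this chain are worth knowing. First, because GC is
logarithmic in coupling power, the amplitude of its phase modulation
saturates at strongly coupled frequencies and peaks where the coupling
signal-to-noise is of order one; the coupled band is therefore identified
from the phase-averaged directed spectrum, while the modulation DAI
carries the direction. Second, 2 Hz multitaper smoothing of a sharp
resonance biases the nonparametric GC peak a few Hz downward (3-5 Hz for
the synthetic 20 Hz coupling); band statements at that smoothing carry
that uncertainty.

## Group inference

The cluster permutation test computes two-tailed one-sample t-values per
point (paired differences or against zero), thresholds at p = 0.05, groups
adjacent suprathreshold points of equal sign (grid adjacency by default,
arbitrary adjacency matrices supported), sums |t| per cluster, and builds
the null from sign-flip permutations with full re-clustering; clusters
exceeding the 97.5th percentile of the maximum-statistic null are
significant. Family-wise error is calibrated at 0.05 on smooth null data
(200 replicates x 500 permutations in the test suite).

Mutual information uses a Gaussian-copula estimator with a discrete
target: continuous predictors are rank-transformed to normal scores
(invariant to monotone transforms), binary cue predictors are centred and
entered linearly, and MI = H(X) - sum_y p(y) H(X|y) from class-conditional
Gaussian entropies. Bias is removed by subtracting the mean MI over 50
outcome shuffles, floored at zero. Brain-behaviour coupling correlates
per-participant coefficient spectra with a behavioural scalar (Spearman by
default) and cluster-corrects over frequency by permuting the participant
pairing.

## The synthetic session

The generator realises the study conditions: 6 runs x 120 trials with 30
per condition per run and exactly balanced target sides; 1600 ms fixation,
50 ms target, 500 ms delay; respiration at 15 breaths/min with log-normal
period jitter (sigma 0.08) and amplitude jitter (sigma 0.1), and sighs
(x2.5-3 amplitude, per-cycle probability 0.02) that exercise the clipping
rule; an observer with base threshold 0.5, slope 0.15, lapse 0.02, and a
0.1-contrast sinusoidal threshold modulation whose sensitivity peak sits
at -pi/3 (late inspiration); QUEST-controlled contrast at criterion 0.60.

ROI epochs are band-limited AR(2) oscillations over a 1/f background
(oscillation variance 1.0, background 0.2). Power modulation scales the
oscillation innovation variance by 1 + d cos(theta - phi_P) using the
phase at target onset — matching the trial-sorting logic of the analyses —
with default depth 0.2 at 10 Hz. Directed coupling injects the lagged
first component of the source ROI into the first component of the target
(VAR(2), cross-term at lag 1) with coefficient
strength x (1 + cos(theta - phase)); defaults (pole radius 0.95, strength
0.15) were set, against the parametric-GC oracle, so the true directed
influence is genuinely band-limited (peak-to-off-band ratio ~4.6 at
20 Hz). The generator emits per-trial VAR coefficient matrices so tests
can compute parametric GC from ground truth. Pupil traces add a
respiration-coupled diameter component and Poisson blinks (area dropouts
of 100-250 ms) with inserted onset times recorded.

What the generator does not emulate: nonstationary observers (drifting
thresholds, fatigue — one reason empirical hit rates in real data sit
below a staircase criterion), cross-frequency structure, source leakage
between ROIs, cardiac contamination, eye movements, or realistic MEG
sensor physics. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not robustness to those
real-data complications.

## Problem sizes and runtime

The default pipeline run (720 trials, 9 channels x 780 samples, 60-window
refit, 30-bin phase-resolved GC) completes in well under a minute on one
CPU. The test suite uses 720-trial sessions for behavioural recovery, 600
trials for power recovery, 480 trials (16 per phase bin) x 20 replicates
for directional GC recovery, 200 replicates x 500 permutations for
cluster-test calibration, and 2000 null draws for circular-test
calibration — sizes chosen so each estimate's sampling error is well
inside the tolerance it is checked against.
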