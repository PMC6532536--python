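# Methods

## The estimation problem

Electrophysiological threshold estimation reduces a set of repeated neural
recordings at graded stimulus intensities to a single number: the lowest
intensity at which the system responds.  The classical workflow — average
the trials per intensity, summarize each average by an amplitude (RMS of an
evoked potential, or a spike rate), fit a sigmoid, and read off where the
fit crosses some criterion level — hides two traps:

1. **Noise-dependent criteria diverge.**  If the criterion references the
   background-noise level (e.g. "response exceeds 2σ"), the threshold
   inherits the noise floor's dependence on the averaging depth.  White
   noise averaged over N trials shrinks as σ_eff = σ₁/√N, so more
   repetitions systematically *lower* the measured threshold, without
   bound: for a logistic response the 2σ threshold falls by c·ln 2 per
   quadrupling of N in the large-N limit.  Labs averaging different trial
   counts then report incomparable thresholds.
2. **Noise and signal must be decoupled correctly.**  An RMS amplitude is a
   power-like quantity; an uncorrelated noise floor adds in quadrature,
   f(x) = √(f₀(x)² + σ²), not linearly.  Treating it additively couples the
   fitted parameters to the noise level.  Spike rates, by contrast, really
   do superpose additively with the spontaneous rate: f(x) = f₀(x) + σ.

## The model

The noise-free level-response function f₀(x) is modelled either as a
generalized logistic

    f₀(x) = a / (1 + exp(−(x − b)/c)),

with maximal response a, inflection intensity b and inverse-slope c, or as
a generalized hard sigmoid

    f₀(x) = 0             x < t
          = s·(x − t)     t ≤ x, s·(x − t) < h
          = h             otherwise,

with lower knee t, slope s and saturation h.  The observable curve is the
composition of f₀ with a **fixed, independently measured** noise floor σ —
quadrature for amplitudes, additive for rates.  σ is estimated from a
recording *without* stimulation and is never a free parameter of the fit:
freeing it makes the threshold estimate unstable because near threshold
signal and noise are nearly exchangeable in the likelihood.

Three criteria convert a fit into a threshold:

* **2σ**: solve f(t) = 2σ.  Closed forms: logistic/quadrature
  t = b − c·ln(a/(√3 σ) − 1); logistic/additive t = b − c·ln(a/σ − 1);
  hard sigmoid t_knee + √3σ/s (quadrature) or t_knee + σ/s (additive).
  Unsolvable when the saturated response cannot reach the criterion level
  (a ≤ √3σ etc.); solvability itself degrades with noise — part of the
  pathology.  Kept for comparison, not recommended.
* **p-fraction**: solve f₀(t) = p·a on the *noise-free* curve (default
  p = 0.05): logistic t = b − c·ln(1/p − 1); hard sigmoid t_knee + p·h/s.
  Depth-independent, but p is arbitrary and moves the answer.
* **knee**: the fitted hard sigmoid's t, read off directly.  No criterion
  parameter at all.  This is the method the package exists for.

## The surrogate-data generator

`standard_surrogate_config()` encodes the validation conditions: logistic
template a = 10 mV, b = 60 dB, c = 11.89 dB, sampled at 22 equally spaced
intensities from −30 to 130 dB; each trial is a 10 ms, 1 kHz sine burst
(200 samples at 20 kHz) whose amplitude follows the template, plus i.i.d.
Gaussian noise of σ₀ = 40 mV per sample; N = 200 trials per intensity plus
a no-stimulus block.  After averaging, the effective floor is
40/√200 ≈ 2.83 mV.

Two amplitude conventions are provided.  In `rms` mode (default) the
template value sets the burst's RMS (peak = √2·f₀), so the recovered curve
saturates exactly at a and the single-trial S/N at saturation is
a/σ₀ = 1/4; in `peak` mode the template sets the peak, and the recovered
curve saturates at a/√2.  The default is `rms` because the stated noise
ratio of the study conditions (S/N = 1/4) and the overlay of template and
recovered curve only hold there; every threshold except the
amplitude-dependent 2σ value is invariant to the choice.

Per-trial noise streams are derived from (seed, block index, trial index)
through `numpy.random.SeedSequence` spawn keys, so datasets are bit
reproducible and any block can be regenerated in isolation, independent of
generation order.

What the generator deliberately does *not* emulate: temporal noise
correlation (real amplifiers band-pass 400–2000 Hz), latency shifts of the
evoked wave with level, stimulus artifacts, or non-sigmoid saturation
behaviour of population responses.  Passing tests therefore demonstrate the
estimator's statistical properties under white noise and a stationary
template — not robustness to every artifact of real recordings (the
double-trial correction and format paths are exercised separately on
constructed fixtures).

## Reduction and the noise floor

Traces: trials are averaged per intensity (phase-inverted double-trial
pairs are averaged against each other first, cancelling stimulus
artifacts), then summarized by the RMS over the half-open analysis window
[0, 10) ms (sample indices floor(start·rate) … floor(end·rate)).  The
default σ estimator pools all no-stimulus single-trial samples in the
window and scales their standard deviation by 1/√N (N = trials averaged
downstream).  The direct alternative — RMS of the averaged no-stimulus
trace — has the same expectation but ~√(samples) times larger estimator
variance and is kept as `method="averaged"` (it is also the quantity the
noise-floor validation checks, ≈ 2.83 mV under the standard conditions).

Spikes: responses are mean evoked rates in the analysis window (default
[0, 200) ms from onset, configurable — the real evoked/spontaneous window
boundaries are a convention, not a measured fact), σ is the spontaneous rate from a pre-stimulus window
or dedicated no-stimulus trials, and composition is additive with no √N
reduction (rates are means, not RMS of averaged noise).

## Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, TRF) on
the composed model with σ fixed; unweighted residuals.  The
quadrature-composed hard sigmoid has gradient kinks at both knees, so the
fit is multi-started: t₀ on a 7-point grid across the sampled range, s₀
from the steepest adjacent-point slope, h₀ from the largest response
(noise-corrected per composition mode); logistic fits start from a b₀ grid
crossed with two c₀ scales.  The lowest-RSS converged start wins; RSS ties
within 1e−10 break towards the smaller threshold parameter, making the
result deterministic for fixed data.  Tolerances 1e−8, 500 function
evaluations per start.  Fits need ≥ 4 points (3 free parameters); a fit
whose threshold parameter lies outside the sampled intensity range is
flagged `extrapolated`, and a fit with no converged start is flagged
`converged=False` and yields no threshold.

## Delete-d jackknife

Uncertainty comes from subsampling: n_subsamples times (default 100), draw
N−d trials per intensity without replacement (independently per intensity
and subsample, seeded from (seed, subsample, block)), re-reduce, re-fit,
re-threshold.  By default σ is re-estimated from the equally subsampled
no-stimulus trials so the model floor tracks the actual averaging depth —
reusing the full-data σ misattributes the elevated shallow-depth noise
floor to signal and biases thresholds downwards catastrophically at small
subsample sizes, which is why re-estimation is the default.  The delete-d
validity criterion √N < d < N is enforced as a warning, not an error
(d ≤ √N draws are still useful for determinism checks).  Undefined
thresholds (unsolvable criterion, non-converged fit) are recorded as NaN,
excluded from quantiles, and counted in `n_defined`.

## Validation protocols and the problem sizes used

`sample_size_sweep` reruns the jackknife at increasing subsample sizes.
Under the 2σ criterion the median threshold decreases strictly with size
(Kendall τ = −1 in practice); the sweep starts at size 70 because below
N = 3σ₀²/a² = 48 the criterion is unsolvable on the standard conditions —
the divergence pathology seen from its other side.  Under the knee and 5%
criteria the medians are flat; the residual systematic trend is measured
as the slope of replicate-averaged medians against log₂ N over sizes
50–200 (several surrogate replicates × 40 subsamples — sizes chosen to
keep the whole validation suite in the minutes range while leaving the
statistics conclusive).  Measured honestly, the knee retains a small
systematic component of ≈ +0.3–0.5 dB per doubling over this range
(shallow-depth subsample medians sit slightly below the full-data
estimate); the 5% criterion's is smaller still, and both are an order of
magnitude below the 2σ criterion's divergence, with the spread (IQR)
shrinking monotonically in depth.

`point_removal_sweep` deletes k reduced-curve points from the
sub-threshold or saturation side before each fit, with identical trial
draws across steps (same seed) so the removal effect is isolated.
Sub-threshold points are redundant once σ is measured separately: removing
all eight of them leaves the knee inside the full-data interquartile
range.  Saturation removal up to "half the dynamic range" (operationalized
as the points whose template response lies strictly between 5% and 95% of
the maximum) moves the knee by ≤ 5 dB; the shift is a genuine small bias
of the piecewise-linear approximation that appears once no saturated point
remains.  The contrast with the symmetric logistic shows up most strongly
in dispersion: under deep saturation removal the logistic 5% threshold's
5–95% band opens to tens of dB while the knee's stays within a few dB.

Known limitation, measured honestly: at intermediate removal steps the
knee's small systematic shift (≈ 2–2.7 dB) can exceed the logistic's
median drift even though the logistic is far less *stable*; median shift
alone is not a sufficient statistic for the robustness contrast.

A second known bias: fitting a hard sigmoid to logistic-shaped data places
the knee ≈ 4.0 dB above the template's 5% point (28.99 vs 24.99 dB on the
noise-free standard template).  The offset is pure approximation error of
the piecewise-linear model, is constant across realizations, and cancels
whenever thresholds are compared across conditions fitted the same way.

## Numerical conventions

* Hard sigmoid evaluated as clip(s·(x−t), 0, h); boundary values at the
  exact knees.
* Intensities are an abstract dB axis; no reference-pressure conversion
  (dB SPL and vibration-amplitude dB are treated identically).
* Negative responses are rejected, not clamped; both model families are
  non-negative by construction.
* Duplicate intensities are averaged at ingestion with a logged notice.
* Windows are half-open [start, end) ms everywhere.
* All stochastic operations take explicit integer seeds; identical seeds
  give bit-identical results.
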