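# kneefit

Objective estimation of sensory thresholds from neurophysiological
level-response data.

## The problem

Whenever a subject cannot report what it perceives — animal experiments,
neonatal audiometry — thresholds must be read out of neural recordings:
auditory brainstem responses, cortical field potentials, single-unit spike
rates.  The conventional recipe (average the trials, fit a sigmoid, mark
where it crosses some criterion) is subjective and noise-entangled:
criteria that reference the background noise (e.g. "response exceeds 2σ")
produce thresholds that *keep falling* as more trials are averaged, because
the effective noise floor shrinks as σ/√N; criteria based on a fixed
fraction of the response range depend on an arbitrary fraction p; and the
symmetric logistic fit destabilizes when the saturation range — often
unmeasurable without harming the subject — is unsampled.

`kneefit` implements a threshold estimator that avoids all three traps:

1. The level-response curve is fitted with a **generalized hard sigmoid**

       f0(x) = 0 for x < t;  s·(x − t) until it reaches h;  h thereafter

   and the **lower knee t is the threshold** — no criterion parameter.
2. The background-noise floor σ is **measured from no-stimulus data and
   held fixed** during fitting, composed with the model in quadrature for
   RMS amplitudes, f(x) = √(f0(x)² + σ²), or additively for spike rates,
   f(x) = f0(x) + σ.
3. Uncertainty comes from a **delete-d jackknife**: repeatedly re-estimate
   the threshold from N−d of the N trials drawn without replacement, and
   report the quantiles of the resulting distribution.

The classical criteria (2σ, p-fraction) and the logistic model are included
for comparison, and a surrogate-data simulator with known ground truth
validates the whole pipeline.

## Worked example

```python
import kneefit as kf

cfg = kf.standard_surrogate_config(seed=1)   # logistic template, sigma0=40 mV, N=200
blocks = kf.simulate_dataset(cfg)            # 22 intensities + no-stimulus block
curve = kf.reduce_to_curve(blocks)           # trial averages -> RMS + measured sigma

fit = kf.fit_level_response(curve, kf.HARD_SIGMOID)
est = kf.threshold_knee(fit)
print(curve.noise.sigma, est.threshold)
```

Running `python examples/01_simulate_and_fit.py` prints

```
measured noise floor sigma : 2.832 mV (expected 40/sqrt(200) = 2.828)
fitted knee t              : 32.93 dB  <- sensory threshold
fitted slope s             : 0.183 mV/dB
fitted saturation h        : 9.60 mV
residual sum of squares    : 0.704
```

The measured floor matches the σ/√N prediction; the knee lands ~4 dB above
the generating template's 5% point (24.99 dB), the constant offset of
approximating a logistic flank with a piecewise-linear model (see
`docs/methods.md`).  `examples/04_sample_size_sweep.py` shows the contrast
that motivates the method:

```
   N   2-sigma median     knee median   knee IQR
  70        79.24 dB       33.01 dB     3.96 dB
 100        70.39 dB       32.48 dB     2.01 dB
 140        64.72 dB       32.51 dB     1.63 dB
 200        60.10 dB       32.37 dB     0.00 dB
```

The 2σ threshold drops ~19 dB as the averaging depth grows (it diverges to
−∞ in the limit, by c·ln 2 ≈ 8.2 dB per quadrupling); the knee stays flat
while only its uncertainty shrinks.

The other examples cover criterion comparison (`02`), jackknife uncertainty
(`03`), robustness to missing supporting points (`05`), and spike-rate data
with additive spontaneous activity (`06`).

## Command line

A thin CLI wraps the same pipeline:

```sh
kneefit simulate --seed 1 --out arch/
kneefit reduce --archive arch/ --out curve.csv
kneefit threshold --archive arch/ --criterion knee --subsamples 100 \
        --subsample-size 180 --out threshold.json
kneefit sweep-samplesize --archive arch/ --criterion 2sigma --model logistic --out sweep.json
```

Formats are plain text: trial archives are directories of CSV matrices
(rows = trials) with a JSON manifest; curves are two-column CSVs with a
`.noise.json` sidecar carrying the measured σ; results are versioned JSON.

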