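"""Threshold estimation from single-unit spiking data.

Spike rates superpose additively with spontaneous activity, so the fit
function is f0(x) + sigma (not the quadrature form used for RMS
amplitudes), with sigma = the spontaneous rate measured in a pre-stimulus
window.  This script builds a synthetic raster from a hard-sigmoid
rate-level template and recovers its knee.
"""

import numpy as np

import kneefit as kf

rng = np.random.default_rng(11)
template = kf.HardSigmoidParams(t=45.0, s=1.2, h=40.0)   # spikes/s
spont = 8.0                                              # spikes/s
intensities = np.arange(30.0, 95.0, 5.0)
n_trials, window_s = 60, 0.2

events = {"x": [], "trial": [], "t": []}
for x in intensities:
    lam = (kf.hard_sigmoid_f0(x, template) + spont) * window_s
    for trial in range(n_trials):
        n_evoked = rng.poisson(lam)
        times = np.concatenate([
            rng.uniform(0.0, 200.0, n_evoked),       # evoked window
            rng.uniform(-200.0, 0.0, rng.poisson(spont * window_s)),  # spontaneous
        ])
        events["x"] += [x] * times.size
        events["trial"] += [trial] * times.size
        events["t"] += list(times)

raster = kf.SpikeRaster(
    intensity=np.array(events["x"]), trial=np.array(events["trial"]),
    time_ms=np.array(events["t"]), n_trials=n_trials,
    analysis_window=(0.0, 200.0), spontaneous_window=(-200.0, 0.0),
)
curve = kf.reduce_to_curve(raster)   # additive composition by default
fit = kf.fit_level_response(curve, kf.HARD_SIGMOID)
est = kf.threshold_knee(fit)

print(f"spontaneous rate (sigma) : {curve.noise.sigma:.2f} spikes/s "
      f"(generator used {spont})")
print(f"noise composition        : {curve.noise.mode}")
print(f"fitted knee              : {est.threshold:.2f} dB "
      f"(generator knee {template.t})")
print(f"fitted saturation        : {fit.params.h:.1f} spikes/s "
      f"(generator {template.h})")
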