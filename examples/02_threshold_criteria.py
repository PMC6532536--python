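"""Compare the three threshold criteria on one fitted curve.

The 2-sigma criterion depends on the noise floor and therefore on how many
trials were averaged; the 5% criterion is noise-free but needs the
arbitrary fraction p; the knee criterion has no free parameter at all.
"""

import kneefit as kf

blocks = kf.simulate_dataset(kf.standard_surrogate_config(seed=1))
curve = kf.reduce_to_curve(blocks)

log_fit = kf.fit_level_response(curve, kf.LOGISTIC)
hs_fit = kf.fit_level_response(curve, kf.HARD_SIGMOID)

two_sigma = kf.threshold_two_sigma(log_fit)
p5 = kf.threshold_p_fraction(log_fit, p=0.05)
knee = kf.threshold_knee(hs_fit)

print(f"2-sigma threshold : {two_sigma.threshold:6.2f} dB  (noise-dependent!)")
print(f"5% threshold      : {p5.threshold:6.2f} dB  (p = {p5.p} is arbitrary)")
print(f"knee threshold    : {knee.threshold:6.2f} dB  (no criterion parameter)")

# The 2-sigma value would keep falling if more trials were averaged:
for n in (200, 800, 3200):
    t = kf.two_sigma_vs_sample_size(log_fit.params, 40.0, n)
    print(f"  closed-form 2-sigma threshold at N={n:5d}: {t:6.2f} dB")
# Each quadrupling of N lowers it by ~c*ln(2) ~ 8.2 dB - the divergence the
# knee criterion eliminates.
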