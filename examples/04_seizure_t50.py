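"""Fit seizure time courses and normalize T50 against a control.

Simulates a heat-seizure assay (cumulative fraction of flies seizing,
scored every 5 min for 80 min) for a susceptible genotype and its background
control, fits the variable-slope sigmoid to each, and reports the
control-normalized T50 ratio.
"""

from comodmap import fit_sigmoid, normalize_t50, simulate_seizure_assay

timepoints = [float(t) for t in range(5, 85, 5)]

control = simulate_seizure_assay(
    true_t50=40, hill_slope=3, n_vials=12, flies_per_vial=5,
    timepoints=timepoints, seed=1, genotype="background",
)
knockdown = simulate_seizure_assay(
    true_t50=30, hill_slope=3, n_vials=12, flies_per_vial=5,
    timepoints=timepoints, seed=2, genotype="knockdown",
)

fit_c = fit_sigmoid(control)
fit_k = fit_sigmoid(knockdown)
print(f"control:   T50 = {fit_c.t50:5.1f} min (logEC50 {fit_c.log_t50:.3f}, "
      f"slope {fit_c.hill_slope:.2f})")
print(f"knockdown: T50 = {fit_k.t50:5.1f} min (logEC50 {fit_k.log_t50:.3f}, "
      f"slope {fit_k.hill_slope:.2f})")
ratio = normalize_t50(fit_k, fit_c)
print(f"normalized T50 ratio = {ratio:.2f}")
# A ratio below 1 means the knockdown seizes earlier than its same-day
# control, i.e. increased seizure susceptibility; the generating truth here
# is 30/40 = 0.75.
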