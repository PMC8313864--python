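"""Simulate an opto-release experiment and refit the shuttling model.

Builds the standard release protocol (5 dark frames, 150 lit, 150 dark at
4 s), simulates compartment proportions with dark-state binding at the
reported medians, adds 1% observation noise, and fits the dual-rate
three-compartment model.  Printed values are the six rate constants (s^-1)
with 95% confidence intervals; they should bracket the generating values.
"""

import optorelease as opt
from optorelease.kinetics import NoiseSpec

rates = opt.default_rates()
schedule = opt.default_protocols("opto-standard")

trace = opt.simulate_trace(rates, schedule, noise=NoiseSpec(frac=0.01), seed=0)
trace = opt.renormalise_per_frame(trace)

fit = opt.fit_opto_model(trace, opt.ModelVariant(on_rate_mode="dual"))

print(f"{'parameter':<14}{'true':>10}{'fitted':>12}  95% CI")
for name in ("k_imp", "k_exp", "k_on_unlit", "k_off_unlit", "k_on_lit", "k_off_lit"):
    lo, hi = fit.conf_int[name]
    print(
        f"{name:<14}{getattr(rates, name):>10.4f}{fit.params[name]:>12.4f}"
        f"  [{lo:.4f}, {hi:.4f}]"
    )
print(
    "\nEach row is a first-order rate constant of the light-switched model;"
    "\nthe dark-state on/off pair sets how strongly the protein is held on"
    "\nthe mitochondria, and k_imp/k_exp set nuclear transit."
)
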