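"""Compare single- vs dual-on-rate models with Akaike weights.

Generates a release trace whose lit-state mitochondrial on rate differs
from the dark-state one, fits both model variants, and prints each
variant's AIC and Akaike weight.  The dual-rate variant should carry nearly
all the weight because the data genuinely contain two on rates.
"""

import optorelease as opt
from optorelease.kinetics import NoiseSpec

rates = opt.RateParams(
    k_imp=0.002, k_exp=0.002,
    k_on_unlit=0.027, k_off_unlit=0.019,
    k_on_lit=0.010, k_off_lit=0.085,
)
schedule = opt.default_protocols("opto-standard")
trace = opt.simulate_trace(rates, schedule, noise=NoiseSpec(frac=0.01), seed=0)
trace = opt.renormalise_per_frame(trace)

variants = [
    opt.ModelVariant(on_rate_mode="single"),
    opt.ModelVariant(on_rate_mode="dual"),
]
results = opt.compare_models_aic(trace, variants)

print(f"{'variant':<24}{'AIC':>12}{'Akaike weight':>16}")
for r in results:
    print(f"{r.variant:<24}{r.aic:>12.1f}{r.akaike_weight:>16.4f}")
print(
    "\nAn Akaike weight > 0.9 for the dual-rate variant says the data"
    "\nstatistically require separate lit and unlit binding kinetics."
)
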