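"""Fit nuclear import/export rates to a synthetic FLIP experiment.

Simulates repeated photobleaching of the nucleus (150 frames at 2 s after 3
pre-bleach frames) with a double-exponential bleach hazard, then fits the
two-compartment model.  Printed values are k_imp and k_exp (s^-1) and the
steady-state nuclear-to-cytoplasmic ratio k_imp/k_exp they imply.
"""

import optorelease as opt
from optorelease.flip import default_flip_times

times, t_bleach = default_flip_times()
true = opt.FLIPParams(k_imp=0.0025, k_exp=0.002, eta1=0.002, eta2=0.02, lam=0.04)

trace = opt.simulate_flip(true, "nucleus", times, t_bleach)
fit = opt.fit_flip(trace)

print(f"{'parameter':<8}{'true':>10}{'fitted':>12}")
for name in ("k_imp", "k_exp"):
    print(f"{name:<8}{getattr(true, name):>10.4f}{fit.params[name]:>12.4f}")
ratio = fit.params["k_imp"] / fit.params["k_exp"]
print(f"\nimplied steady-state N/C ratio: {ratio:.3f}")
print(
    "The ratio above equals the pre-bleach nuclear-to-cytoplasmic intensity"
    "\nratio: FLIP pins the import/export balance even though both pools are"
    "\nlosing fluorescence to the bleach."
)
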