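"""Estimate diffusivity and mitochondrial binding from a synthetic FRAP run.

Simulates a circular-spot photobleach (2.6 um diameter, 0.5 s frames) in an
elliptical cytoplasm and fits the reaction-diffusion model.  Printed values:
the diffusivity (um^2/s), the binding rate constants (s^-1) and the implied
equilibrium bound fraction k_on/(k_on+k_off).
"""

import numpy as np

import optorelease as opt
from optorelease.synthkit import _ellipse_mask

mask = _ellipse_mask((96, 96), (48, 48), (42, 36)) & ~_ellipse_mask(
    (96, 96), (48, 48), (15, 12)
)
geom = opt.FRAPGeometry(mask, pixel_size_um=0.13)
protocol = opt.BleachProtocol(
    bleach_profile=opt.make_bleach_profile(10, "empirical-like"),
    roi_center=(48, 78),
    roi_radius_px=10,
    frame_interval_s=0.5,
    n_prebleach=5,
    n_recovery=40,
)
true = opt.FRAPParams(D_c=30.0, k_on=0.027, k_off=0.019, alpha=3.0)
series = opt.simulate_frap(geom, true, protocol)

guess = opt.FRAPParams(D_c=15.0, k_on=0.05, k_off=0.01, alpha=2.0)
fit = opt.fit_frap(series, protocol, init_guess=guess)

print(f"{'parameter':<8}{'true':>10}{'fitted':>12}")
for name, t in [("D_c", 30.0), ("k_on", 0.027), ("k_off", 0.019), ("alpha", 3.0)]:
    print(f"{name:<8}{t:>10.3f}{fit.params[name]:>12.3f}")
bf = opt.bound_fraction(fit.params["k_on"], fit.params["k_off"])
print(f"\nequilibrium bound fraction: {bf:.3f}")
print(
    "A bound fraction near 0.59 means the dark-state equilibrium favours"
    "\nmitochondrial sequestration, which is what makes light release useful."
)
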