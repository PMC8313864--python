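"""Segment a synthetic release movie and extract compartment signals.

Renders a three-channel movie (protein, mitochondrial and nuclear markers)
of a synthetic epithelial-like cell under the standard release protocol,
segments it with moving percentile projections and interpolated thresholds,
and prints per-compartment mask overlap with ground truth plus the
correlation between extracted and generating proportions.
"""

import numpy as np

import optorelease as opt

spec = opt.SyntheticCellSpec(
    image_shape=(160, 160),
    cell_axes_px=(62.0, 50.0),
    nucleus_axes_px=(21.0, 17.0),
    nucleus_offset_px=(6.0, 5.0),
    seed=0,
)
rates = opt.default_rates()
schedule = opt.default_protocols("opto-standard")

trace = opt.simulate_trace(rates, schedule)
geometry = opt.make_cell_geometry(spec)
stack, truth = opt.render_movie(geometry, trace, spec)

masks = opt.segment_compartments(stack, opt.WindowProfile(n_seeds=2))

print("mask overlap with ground truth (Jaccard):")
for name in ("cell", "nucleus", "mitochondria", "cytoplasm"):
    est, gt = getattr(masks, name)[0], getattr(geometry, name)
    j = (est & gt).sum() / (est | gt).sum()
    print(f"  {name:<14}{j:.3f}")

raw = opt.extract_signals(stack, masks, schedule)
norm = opt.renormalise_per_frame(opt.bilinear_normalise(raw))
print("\ncorrelation of extracted vs generating proportions:")
for name, est, gt in zip("MCN", norm.stacked(), trace.stacked()):
    print(f"  {name}: r = {np.corrcoef(est, gt)[0, 1]:.4f}")
print(
    "\nJaccard near 1 and r near 1 mean the percentile-window segmentation"
    "\nrecovers the compartments and their dynamic signals faithfully."
)
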