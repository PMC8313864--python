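# optorelease

Quantification of nucleocytoplasmic shuttling kinetics from optogenetic
release ("opto-release"), FRAP and FLIP time-lapse microscopy.

## The problem

In an opto-release experiment a Zdk-tagged fluorescent protein is
sequestered on the outer mitochondrial membrane by a dark-state LOV domain
(the LOVTRAP pair), released into the cytoplasm by blue light, and
re-sequestered in the dark. Watching the protein redistribute between
mitochondria, cytoplasm and nucleus turns a single movie into an assay for
first-order nuclear import and export rate constants — quantities that are
otherwise hard to separate from binding and diffusion. This package
implements the full desk-side analysis:

- **Segmentation** of multi-channel movies (protein + mitochondrial +
  nuclear markers) with moving percentile-window projections, seeded
  thresholds interpolated across frames, and a hybrid max-projection channel
  for the cell boundary.
- **Normalization**: background subtraction and bleaching correction by a
  per-phase linear ("bilinear") fit to total cell intensity, converting
  intensities to proportions of total signal.
- **Kinetic models and fitting**:
  - the light-switched three-compartment ODE

    ```
    dM/dt = k_on C  - k_off M
    dC/dt = k_off M - k_on C + k_exp N - k_imp C
    dN/dt = k_imp C - k_exp N
    ```

    with (k_on, k_off) taking lit- or dark-state values;
  - the FRAP reaction–diffusion PDE
    `∂c/∂t = D_c ∇²c − k_on c + k_off m − αI c`,
    `∂m/∂t = k_on c − k_off m − αI m` with zero-flux boundaries, solved by
    masked Crank–Nicolson with exact binding-exchange splitting;
  - the FLIP two-compartment ODE with a double-exponential bleach hazard
    `h(t) = η₁ + η₂ e^{−λt}` acting on the bleached compartment.
- **Model selection** by AIC (`n ln(RSS/n) + 2k`) and Akaike weights, over
  single- vs dual-on-rate and free- vs fixed-dark-rate variants.
- **Regional analysis**: 16-bit gain maps (post/pre × 256) and averaging of
  repeated-pulse responses.
- **Synthetic data**: a generator that stands in for the microscope —
  elliptical cell, filamentous mitochondrial network, ODE-driven channel
  intensities, per-phase linear photobleaching, seeded detection noise —
  with ground truth attached to every movie.

It is aimed at quantitative cell biologists analysing LOVTRAP-style
release experiments and at modellers who want a testable reference
implementation of the three kinetic models.

## Worked example

`examples/simulate_and_fit_release.py` simulates the standard protocol
(5 dark + 150 lit + 150 dark frames at 4 s) with 1% noise and refits it:

```
parameter           true      fitted  95% CI
k_imp             0.0020      0.0020  [0.0020, 0.0020]
k_exp             0.0020      0.0020  [0.0020, 0.0020]
k_on_unlit        0.0270      0.0273  [0.0264, 0.0282]
k_off_unlit       0.0190      0.0192  [0.0186, 0.0199]
k_on_lit          0.0270      0.0272  [0.0260, 0.0284]
k_off_lit         0.0850      0.0856  [0.0819, 0.0893]
```

Each row is a rate constant in s⁻¹: the dark-state on/off pair
(0.027/0.019) quantifies mitochondrial sequestration — a bound fraction of
0.027/(0.027+0.019) ≈ 0.59 at equilibrium — the lit off rate is the
light-accelerated release, and k_imp/k_exp set nuclear transit. The other
example scripts cover FRAP fitting (`frap_diffusion_and_binding.py`), FLIP
(`flip_import_export.py`), segmentation (`segment_synthetic_movie.py`),
AIC model comparison (`model_selection.py`) and regional maps
(`regional_release_maps.py`).

A thin CLI wraps the same functions for shell use:

```bash
optorelease simulate --seed 1 --out run/
optorelease segment --stack run/movie.tiff --out run/
optorelease fit-opto --trace run/raw_trace.csv --schedule run/schedule.json --out run/
```

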