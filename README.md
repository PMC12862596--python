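# shgqpm

Quasi-phase-matching (QPM) modelling of second harmonic generation (SHG)
image contrast in fibrillar collagen.

SHG microscopy resolves collagen *fibers* (~µm), but the coherent physics
of the signal is set by the sub-resolution *fibrils* (~50–240 nm): their
size, packing and polarity determine how much second harmonic is emitted
forward versus backward (F_SHG/B_SHG) and how efficiently light is
converted across the near-infrared. `shgqpm` computes these creation
attributes from first principles for biomimetic fibril architectures, so
that measured emission directionality and wavelength dependence can be
used to place bounds on fibril structure without electron microscopy. It
is aimed at researchers modelling SHG contrast in collagenous tissue
(tendon, ovary, cornea, stroma) and at anyone needing accurate Fourier
decompositions of discontinuous structures.

## Model

Fibrils are polar cylinders (normalized susceptibility ±1) in a focal box,
orthogonal to a focused Gaussian fundamental propagating along z. With the
structure expanded as g(r) = Σ G_mnl e^{i k_mnl·r}, the far-field harmonic
amplitude in direction (θ, φ) is

    E_2ω ∝ i (π/2)^{3/2} (2ω w_ρ² w_z / c n_2ω) d_eff E_ω²
           Σ_mnl G_mnl e^{−Δk_x² w_ρ²/8} e^{−Δk_y² w_ρ²/8} e^{−Δk_z² w_z²/8}

with Δk_z = 2ξk_ω − k_2ω cosφ + k_mnl,z and the transverse components
−k_2ω cosθ sinφ + k_mnl,x, −k_2ω sinθ sinφ + k_mnl,y. Because real fibril
packings are not crystals, the G_mnl are computed numerically with a
*discontinuous* fast Fourier transform: piecewise Gauss–Legendre
quadrature between exact geometric jump locations, which avoids the
ringing that makes a plain FFT useless here (its emission peak comes out
orders of magnitude low on discontinuous structures). Emission patterns
are segmented into lobes and F/B ratios and integrated intensities are
computed as the volumes enclosed by the radial plot r = I(θ, φ).
See `docs/methods.md` for the full treatment and the numerical choices.

## Worked example

```python
from shgqpm import (
    FibrilEnsembleSpec, DEFAULT_BOX, OpticalConfig,
    generate_random, voxelize, compute_emission, metrics_from_pattern,
)

spec = FibrilEnsembleSpec(
    mean_diameter=60.0,      # nm
    diameter_sd_frac=0.0,
    fill_fraction=0.25,      # quarter of the cross-section
    polarity_mode="random",
    seed=1,
)
model = generate_random(spec, DEFAULT_BOX)   # 1.4 x 1.4 x 6 um box
print(f"{model.n_fibrils} fibrils, achieved fill {model.fill_fraction:.4f}")

volume = voxelize(model, grid_dims=(50, 50, 150))
pattern = compute_emission(model, volume, OpticalConfig(lambda_fund=800.0))
m = metrics_from_pattern(pattern)
print(f"F/B = {m.FB_ratio:.2f}  ({m.n_lobes} lobes, "
      f"forward {m.F_total:.3g}, backward {m.B_total:.3g})")
```

prints

```
743 fibrils, achieved fill 0.2501
F/B = 3.17  (6 lobes, forward 1.97e+26, backward 6.22e+25)
```

743 non-overlapping 60 nm fibrils fill a quarter of the focal
cross-section; at 800 nm this random-polarity ensemble emits about three
times more volume forward than backward — inside the range measured in
real tissues (~1–10). Flipping every polarity to "aligned" drives F/B up
by several orders of magnitude, which is one of the model's core
predictions: polarity disorder, not fibril placement, controls the
emission pattern. (Volumes are in relative units — intensity cubed times
solid angle — so only ratios and trends are meaningful.)

The same machinery is scriptable from the command line:

```bash
shgqpm validate                 # periodic-structure validation suite
shgqpm sweep --config cfg.yaml  # diameter/density/variation sweeps -> CSV
shgqpm heterogeneity            # 10-seed replicate variability
shgqpm lattice-compare          # polarity clustering vs fibril placement
shgqpm pattern --diameter 120 --density 0.25 --out pattern.h5
```

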