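# Methods

`shgqpm` predicts the creation attributes of second harmonic generation
(SHG) in fibrillar collagen — the 3D spatial emission pattern, the
forward/backward ratio F_SHG/B_SHG, and the relative conversion
efficiency — from a generalized quasi-phase-matching (QPM) treatment that
admits non-ideal phase mismatch and non-periodic, biomimetic fibril
architectures.

## Model

Starting from the coupled-wave equation for SHG in the slowly varying
envelope approximation with an undepleted fundamental, the spatially
varying effective susceptibility d(r) = d_eff · g(r) is expanded in a
Fourier series over the simulation box, g(r) = Σ G_mnl exp(i k_mnl · r)
with k_mnl = (2πm/L, 2πn/W, 2πl/H). The focused fundamental is a Gaussian
envelope exp(−(x²+y²)/w_ρ² − z²/w_z² + iξk_ω z), where ξ ∈ (0, 1] is an
empirical factor standing in for the Gouy phase anomaly. Integrating the
driven harmonic field over all space gives the closed-form far-field
amplitude in direction (θ, φ):

    E_2ω(θ, φ) = i (π/2)^{3/2} (2ω w_ρ² w_z / c n_2ω) d_eff E_ω²
                 × Σ_mnl G_mnl exp(−Δk_x² w_ρ²/8) exp(−Δk_y² w_ρ²/8)
                                exp(−Δk_z² w_z²/8),

with the directional mismatch

    Δk_z = 2ξk_ω − k_2ω cos φ + k_mnl,z,
    Δk_x = −k_2ω cos θ sin φ + k_mnl,x,
    Δk_y = −k_2ω sin θ sin φ + k_mnl,y.

Intensity is |E|². Because each Gaussian weight depends on one momentum
index and at most both angles, the triple sum is evaluated as staged
tensor contractions (z factor against φ first), which makes the 200×200
angular grid cheap even with ~10⁴ retained components.

Assumptions inherited from this formulation: scalar χ⁽²⁾ (no polarization
resolution), undepleted monochromatic fundamental, cylindrical fibrils
perpendicular to the beam spanning the focal box, no resonance dispersion
of d_eff (constant with wavelength), and free-space propagation of the
harmonic (no collection-optics clipping, no tissue scattering).

## Optical parameters

* Dispersion: n(λ) = 1.4389 + 1.588·10⁴/λ² − 1.4806·10⁹/λ⁴ + 4.3917·10¹³/λ⁶
  (λ in nm), the empirical rat-tail tendon fit. The λ⁶ reading of the last
  term is the default: with λ⁴ the term is ~10² at 800 nm and the index is
  unphysical (n > 100); with λ⁶ it gives n(800) ≈ 1.4603, the accepted
  collagen value. The λ⁴ dialect remains selectable
  (`DispersionModel(last_term_exponent=4)`) for auditing.
* n_2ω comes from the same formula at λ/2; normal dispersion then makes
  the backward coherence length (2π/|2ξk_ω + k_2ω| ≈ 140 nm at 800 nm) far
  shorter than the forward one (2π/|2ξk_ω − k_2ω| ≈ 13 µm).
* Beam waists: w_ρ = 0.320λ/(√2 NA) for NA ≤ 0.7, 0.325λ/(√2 NA^0.91)
  above (branch mismatch < 2% at the breakpoint);
  w_z = (0.532λ/√2)·1/(n_ω − √(n_ω² − NA²)), evaluated with tendon n
  (whether an immersion-medium index should be used instead is
  undocumented in the source formulas; tendon n is used throughout).
* NA defaults to 0.8 (typical SHG microscopy; consistent with the fixed
  1.4 × 1.4 × 6 µm box being ≈ 4 beam waists per axis across the sweep).
* ξ defaults to 1.0 and is an explicit, reported configuration value; the
  emission pattern shifts smoothly with ξ (the backward QPM condition
  moves as 2ξk_ω), and nothing in the validation fixtures constrains it.

## Structures

Fibrils are hard disks in the (y, z) cross-section extruded along x.

* Random ensembles: rejection sampling (random sequential adsorption) with
  a cell-list; centres uniform over the admissible region, radii from a
  normal distribution (SD a stated fraction of the mean) truncated at ±3σ
  and r > 0 — truncation avoids non-physical negative radii. Disks are
  added until the achieved cross-sectional fill reaches the target; the
  final overshoot (< 0.6% absolute even for 240 nm fibrils) is well inside
  the ±2% acceptance band. At fill = 1/2 the sampler operates near the RSA
  jamming limit (~0.547), so the per-fibril attempt budget is 10⁵; a
  stalled packing raises a `PackingError` naming the achieved fraction.
  "Density"/"fill" is cross-sectional area fraction, which equals volume
  fraction since fibrils span the box.
* Lattices: near-square lattice with ideal period a = d√(π/4f) rounded per
  axis to an integer cell count; shifted lattices draw one uniform offset
  in [−A, +A]² per fibril, redrawing (bounded) on overlap or box exit.
  Polarity modes: aligned (+1), i.i.d. random ±1, or checkerboard in
  lattice indices.
* Voxelization: centre-inclusion on the grid (default 100×100×300; the
  shipped studies use 50×50×150 — see "Problem sizes"). No anti-aliasing:
  the spectral path never relies on rasterized boundaries (below), so the
  voxel field only carries the smooth focal window and the ±1 values.
* Focal window: the structure is multiplied by the separable Gaussian
  exp(−a(x²+y²)/w_ρ² − a z²/w_z²), a = 1 (field envelope, default) or
  a = 2 (squared-field envelope). With the printed box and a = 1 the
  window at the axial faces is ~3.5·10⁻³ at 800 nm (weaker at 1200 nm);
  edge effects at this level are visible only below the default pruning
  threshold.

## Window convention

The two-step procedure — window the structure with the field envelope
(a = 1), then apply the closed-form Gaussian weights — is the package
default (`window_mode="windowed"`). The alternative `"weights_only"` mode skips
the structure window and is appropriate when feeding exact periodic series
components. On the 1D validation fixture both conventions reproduce the
closed-form emission peak to ~10⁻⁵% (the DFFT is accurate enough that the
choice cannot be discriminated there), so the default follows the
two-step description the model was built around. The double-counted
axial envelope in "windowed" mode narrows the effective QPM acceptance width
(w_z²/8 → w_z²/12 against the un-windowed series); comparisons are
therefore always made like-for-like within one mode.

## Discontinuous Fourier transform (DFFT)

The structure is discontinuous at fibril boundaries, so a uniform-sample
DFT rings (and, as usually applied, references phases to the array corner
rather than the box centre, which scrambles component signs — the shipped
reference path `dft_3d_reference` reproduces exactly this standard
behaviour for comparison; on the 1D fixture its emission peak is ~4.6
orders of magnitude low). Instead, each 1D transform is evaluated
piecewise between geometrically known jump locations:

* per smooth piece, Gauss–Legendre quadrature of ∫ f(u) e^{−iku} du with
  the exponential evaluated exactly at the nodes;
* f at each node from local Lagrange interpolation (order p = 2) of the
  voxel samples, with stencils restricted to samples strictly inside the
  piece (samples falling exactly on a jump are ambiguous and excluded);
* jump locations from exact geometry: disk chord entry/exit per y line,
  disk extrema c_z ± r along z, prism faces per axis — never detected
  numerically. Boundaries closer than one sample pitch are merged with a
  warning.

The quadrature order is capped at q = 128 per piece, with short pieces
using proportionally fewer nodes (two nodes per sample pitch plus margin —
enough to resolve anything the p = 2 interpolant can represent). The 3D
transform applies the 1D pass separably along x, y, z; per-line plans
(nodes, weights, stencil coefficients) are cached and reused across the
batch and across wavelengths. Components are normalized per unit box, so
G_000 is the structure mean and Σ G e^{+ik·r} reconstructs the structure.

Accuracy: on the 1D fixture retained components agree with adaptive
quadrature of the continuous profile to ~10⁻⁷ relative; on a piecewise-
smooth 3D prism instance to ~10⁻⁴. For cylinders the chord profile has
square-root kinks at disk tangent points, which the sampled separable
transform resolves only first-order in the voxel pitch: top-component
errors are ~4% at 25 nm pitch falling to ~0.5% at 6 nm pitch. This is the
same error class as the 0.73–6.18% band seen in the 3D lattice validation
and is inherent to sampling, not to the quadrature. At q ≥ 16 the error is
interpolation-limited (raising q further changes nothing); quadrature
becomes limiting only at very low orders (q ≈ 2–4).

Only momenta that can contribute to the emission are computed and kept:
the Gaussian weights bound every component's influence by
exp(−w_min²·dist²/8), dist = ||k_mnl + (0,0,2ξk_ω)| − k_2ω|, giving
per-axis index windows (`select_index_ranges`) and a conservative pruning
rule (`prune`, relative threshold 10⁻⁶; pruning at 10⁻⁶ changes the peak
intensity by < 0.1%, and ε = 0 disables it).

## Lobe metrics

The angular pattern is read as a radial plot r = I(θ, φ). The intensity
profile around the x–z great circle (where the dominant lobes lie) is
scanned for local minima with prominence ≥ 1% of the global peak; their
inclinations, plus the hemisphere boundary π/2, partition [0, π] into
bands, and each band × hemisphere is one lobe (cells below 10⁻⁶ of the
peak stay unassigned; φ = π/2 counts as forward — a fixed tie-break). The
band rule is a documented choice: it is exact for patterns whose lobes are
stratified in inclination and approximates strongly azimuth-asymmetric
patterns by their inclination structure.

Lobe volume defaults to the exact solid-angle integral V = Σ I³ sinφ
ΔφΔθ / 3 (the volume enclosed by the radial surface over the lobe's grid
cells, deterministic and grid-exact). A `boundary_triangulation` method
(convex hull of the lobe point cloud plus the origin) mirrors
triangulation-based procedures and agrees within 5% on smooth convex
lobes; degenerate lobes fall back to the solid-angle integral with a
warning. F_SHG/B_SHG divides summed forward volumes by backward ones
(+∞ preserved and flagged when the backward hemisphere is empty;
aggregations then use medians or exclude non-finite values with a count);
integrated intensity is their sum.

## Wavelength sweeps and excitation normalization

`wavelength_series` fixes the structure and rebuilds window, geometry,
spectrum and pattern per wavelength. The Eq.-form prefactor at constant
field amplitude scales as ω w_ρ² w_z ∝ λ², and the cubic volume metric
amplifies that to λ⁶ — which would swamp the structural wavelength
response. Relative conversion efficiencies are comparable across
wavelengths only at fixed focused laser power, so sweeps default to
`excitation="constant_power"` (E ∝ 1/w_ρ, normalized at the first
wavelength; the prefactor is then nearly wavelength-flat and the measured
trend is the structure factor's). `constant_field` is available for
single-wavelength or prefactor studies. With constant power, integrated
intensity falls from 800 to 1200 nm for the typical random ensemble, and
the F/B ratio is far more replicate-sensitive than the integrated
intensity (CV larger at every wavelength in the shipped heterogeneity
study) — directionality encodes the specific realization, conversion
efficiency mostly the parameter set.

## Problem sizes and determinism

The shipped studies and the acceptance script use the printed
1.4 × 1.4 × 6 µm box rasterized at 50 × 50 × 150 voxels with pruning on, a
200 × 200 angular grid, and 3-replicate (sweeps) or 10-replicate
(heterogeneity) seeds derived as base_seed + replicate. A full single
model-wavelength evaluation takes ~1 s on one core at 100 × 100 × 300 and
~0.2 s at the reduced grid; the reduced grid changes validation errors at
the 0.1% level because the spectral path uses exact geometry. Every
generator is a pure function of (spec, seed); identical configurations
reproduce identical tables bit for bit.

## Known limitations

* The 3-seed mean of F/B for 60 nm / 1/4 fill ensembles does not reliably
  resolve the (real, but small) increase with 20% diameter spread: F/B is
  heavy-tailed across seeds (CV ≳ 1, range spanning 0.03–100 at fixed
  parameters), so small-sample mean comparisons of that clause are
  underpowered; the corresponding check is kept at its stated 3-seed
  design and currently fails, while 12-seed means/medians show the
  increase. Diameter and polarity effects are orders of magnitude and
  robust at 3 seeds.
* Synthetic structures omit fibril crimp, tilt, finite length, D-period
  substructure and any interfibrillar correlation beyond hard-disk
  exclusion; passing trend tests shows the model's response to size,
  packing, polarity and wavelength, not fidelity to any particular
  tissue's microstructure.
* The scalar treatment cannot address polarization-resolved observables.
* Measured F/B in tissue couples the creation-level ratio computed here
  with photon transport; no scattering model is included.
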