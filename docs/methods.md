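# Methods

## Scope and model

`darkfield` simulates x-ray dark-field (DF) radiography of lung tissue in a
symmetric Talbot grating interferometer and estimates the linear diffusion
coefficient ε of the tissue from simulated thickness series.  The imaging
chain is monochromatic scalar wave optics in the projection approximation:

1. a unit plane wave ψ₀ ≡ 1 on a fine transverse grid;
2. multiplication by the object transmission
   O = exp(i·(2π/λ)∫δ dz − (2π/λ)∫β dz), with the line integrals taken
   through a random-sphere lung slab (air spheres in muscle tissue);
3. multiplication by the π-phase grating G1 (rectangular profile, duty 0.5);
4. angular-spectrum propagation over the first fractional Talbot distance
   d = m·p₂²/(2λ) to the analyzer plane (Ĥ = exp(−iπdλ(u²+v²)), periodic
   boundary, unitary);
5. per analyzer step x_G2: multiplication of |ψ|² by the binary G2
   transmission train (pitch p₂, duty 0.5, ideal absorbing bars), pixel
   binning, exposure scaling, optional MTF/focal-spot blur and NPS-shaped
   Poisson-scaled noise;
6. per-pixel discrete Fourier analysis of the stepping curve (mean a₀,
   first harmonic a₁, phase φ; visibility v = 2a₁/a₀), and the image ratios
   T = a₀/a₀ʳᵉᶠ, df = v/vʳᵉᶠ, Δφ = wrap(φ − φʳᵉᶠ).

The autocorrelation length ξ = λd/p₂ equals m·p₂/2 ≈ 1 µm at the first
Talbot order for p₂ = 2 µm in both configurations, so both systems probe
micrometre-scale structure regardless of energy.

ε is defined through the exponential thickness law

    −log df = (2π²d²/p₂²) · ε · t,

fitted over six slab thicknesses by zero-intercept least squares (see
below).

## Lung phantom

The parenchyma is a slab of muscle tissue filled with monodisperse air
spheres of diameter S (39/60/80 µm for the murine presets, 200/300/400 µm
for the human presets), zero wall thickness.  Sphere centres are uniform
over the lateral extent and over z ∈ [0, t]; overlap is permitted.  The
sphere count realizes a *nominal* (sum-of-volumes) volume fraction
f = 0.56: count = round(f·A·t / ((4/3)π(S/2)³)).  This convention gives
exactly 325/89/38 spheres per 100 µm pixel per 1.8 mm (murine diameters)
and 75/22/9 per 150 µm pixel per 25 mm (human diameters).  The realized
union air fraction is lower, ≈ 1 − e^(−f) ≈ 0.43, and is reported as a
diagnostic.

**Projection semantics.**  Two analytic projections of the pack onto the
fine grid are provided, both clipping every chord to the slab faces:

* *additive* (`project_chord_sum`, the study default): every sphere
  contributes its full chord independently; overlap regions are double
  counted.  Physically this treats each alveolus as an independent
  scatterer whose phase contribution adds, which is the reading under which
  the per-pixel count convention, the printed ε values and the DF levels at
  maximum thickness are all mutually consistent.  At murine settings
  (60 µm, t = 10.8 mm) it yields df ≈ 0.25.
* *union* (`project_air_path`): chord intervals are merged exactly (no
  double counting), so the air path is bounded by t.  This is the
  geometrically exact porosity of the overlapping-sphere solid; it
  de-correlates the wave roughly half as fast (df ≈ 0.50 at the same
  murine settings) because overlap removal suppresses the phase variance of
  a dense pack.  It is validated in the tests against a brute-force
  z-marching voxel oracle and serves as the porosity diagnostic.

The difference between the two is a genuine modelling choice for
interpenetrating alveoli; the additive form is the default because it is
the one consistent with the study's quantitative DF response.

## Geometry choices

* **G1 pitch.**  The presets use the plane-wave-equivalent p₁ = 2·p₂ =
  4.000 µm, whose self-image period matches the analyzer pitch exactly.  A
  physical instrument with p₁ = 3.901 µm and a diverging beam magnifies its
  1.9505 µm self-image onto the 2.000 µm analyzer; in a strictly plane-wave
  model the unmagnified mismatch creates a ~79 µm moiré which (worse than a
  mere visibility penalty) biases df upward, because the object-broadened
  fringe spectrum leaks into the analyzer passband while the reference
  suffers the full mismatch washout.  The physical pitch remains settable
  for studies of exactly that artifact.
* **Talbot distance.**  d = m·p₂²/(2λ) (π-grating fractional distance),
  giving 4.47 cm at 27.7 keV and 10.40 cm at 64.5 keV for p₂ = 2.000 µm.
* **Grid.**  Fine spacing p₂/fine_sampling (default 16 samples per period,
  8 minimum — coarsening from 16 to 8 under-resolves the sphere-rim phase
  structure and lowers the fitted ε by ~10–15%, so 8 is a quick-look mode,
  not a study setting); periodic guard band ≥ 32 p₂ per side, widened
  to an FFT-friendly length and cropped before binning.  The phantom covers
  the padded grid plus one sphere diameter so guard-band statistics are
  homogeneous; at these Fresnel numbers wrap-around displaces light by only
  ~µm, far below the guard width.
* **Phase stepping.**  8 uniform steps over one p₂ period by default (any
  N ≥ 3); with sampling commensurate with p₂ the steps are exact sample
  shifts.

## Optical constants

δ and β are inputs per material and energy.  The 27.7 keV values (muscle
δ = 3.10e-7, β = 1.78e-10; air δ = 2.71e-10, β = 1.42e-13) are standard
tabulations.  The 64.5 keV decrements are obtained from the 27.7 keV values
by the λ² law δ ∝ λ² that holds far from absorption edges
(δ = r_e λ² n_e/2π), giving muscle δ = 5.72e-8 and air δ = 5.00e-11; these
agree with a first-principles evaluation from the ICRP muscle/air electron
densities at 64.5 keV.  β values at 64.5 keV are taken as tabulated
(absorption affects transmission, not df, so the df results are insensitive
to them).

## Detector model

The default detector is ideal: MTF ≡ 1, flat NPS, zero focal-spot blur,
noise disabled, exposure 10³ mGy with unit calibration.  The study design
deliberately works in the noise-free limit (high exposure), so system
visibility accuracy is not required; measured MTF and NPS curves
(two-column text, cycles/mm vs value) are opt-in.  Noise, when enabled,
follows the measured-NPS construction: a unit-variance Gaussian field is
filtered by √NPS, renormalized to unit empirical standard deviation, scaled
pointwise by √intensity (Poisson magnitude) and added.

## ε estimation

For each thickness and repetition a fresh sphere pack is generated
(seed = base_seed + cell index, cells enumerated thickness-major), the
object and reference stacks are acquired, and df is averaged over all
field-of-view pixels (plain arithmetic mean).  −log(mean df) is regressed
on t through the origin.  The default is ordinary least squares — the
convention of standard curve-fitting software, and the replication-faithful
choice; inverse-variance weighting by the repetition scatter is available
as an option and differs by a few percent on these slightly saturating
series.  ε = slope/(2π²d²/p₂²); its standard error is the slope standard
error divided by the same factor, and r² is the uncentered coefficient of
determination of the through-origin fit.  A free-intercept fit is reported
as a diagnostic (its intercept is a saturation/edge-effect indicator).
Single-ROI inversion (`epsilon_from_roi`) and the forward prediction
(`predict_df`) implement the same law point-wise.

## What the simulation does and does not emulate

The synthetic phantom reproduces the *statistics* that drive the dark-field
signal — sphere size, nominal volume fraction, slab thickness — under
monochromatic plane-wave illumination with idealized gratings.  It does not
model: polychromatic spectra or beam hardening; cone-beam magnification or
finite source size (G0 apertures default to zero width); ribs, skin, fur or
any anatomy beyond the slab; polydisperse or non-spherical alveoli;
alveolar walls; grating imperfections.  Passing tests therefore demonstrate
internal consistency of the wave chain and stability of the simulated
study, not quantitative agreement with any particular physical scanner,
whose ε values shift with magnification, focal-spot blur and spectrum.

## Problem sizes and numerical choices

Full-study presets use 5×5 (murine) or 10×10 (human) pixel fields of view,
16 samples per p₂ and 10 repetitions.  The package's own acceptance runs
and the heavy tests use a reduced desk scale — 2×2 pixels, 16 samples per
p₂, 3 repetitions, all six thicknesses, noise off — which leaves the
estimand unchanged and only widens the stochastic scatter (the `--scale`
CLI knob applies the same reduction, additionally dropping to 8 samples per
p₂ for speed).  Diameter-ordering checks run at 1 repetition, 3 thicknesses
and 8 samples per p₂.  At the 2×2-pixel desk scale with full sampling the
fitted medium-diameter coefficients are murine ε ≈ 1.31e-11 /mm and human
ε ≈ 1.0e-13 /mm, with a murine/human ratio ≈ 125–135; the reduced scale
changes these by well under the ~±5% seed-to-seed scatter of three
repetitions.

Numerical details: chord projections are analytic per sample (a compiled
row-sweep kernel; the union variant merges nearly-sorted intervals in
linear time); propagation uses `scipy.fft` on FFT-friendly padded sizes;
pulse trains snap samples landing on a grating edge with a 1e-9 relative
epsilon so commensurate grids classify edges consistently at every step;
df values marginally above 1 are kept unclipped so averages stay unbiased.

## Known limitations

* The additive projection lets the local air path exceed t in rare deep
  overlaps; the transmission formula extrapolates linearly there.
* The simulated −log(df) series bend slightly below linearity at the
  largest thicknesses (non-Gaussian saturation of the phase-difference
  distribution), so the fitted ε depends a few percent on the weighting
  convention; r² nevertheless exceeds 0.99 at study settings.
* Reference visibility depends on duty cycles and bar transmission, which
  are idealized; only the *ratio* df is quantitative.
* A 1-pixel-high field of view gives a valid quasi-1-D fast mode but
  under-samples the 2-D phantom statistics; it is used only in tests.
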