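# darkfield

Wave-optics simulation of x-ray dark-field (DF) lung radiography with a
Talbot grating interferometer, and estimation of the lung tissue **linear
diffusion coefficient** ε from simulated thickness series.

## The problem

Grating-interferometry dark-field imaging visualizes small-angle scattering
from sub-pixel structure — in the lung, the millions of air–tissue
interfaces of the alveoli.  It works spectacularly in mice; whether it
survives the translation to human imaging is not obvious, because human
alveoli are ~5× larger (200–400 µm vs 39–80 µm) and the autocorrelation
length ξ = λd/p₂ of a realistic interferometer stays near 1 µm, far below
either alveolar size.  This package answers that question *in silico*: it
simulates the full imaging chain — object transmission, π-phase grating G1,
Fresnel propagation to the analyzer G2, phase stepping, pixel integration,
detector blur/noise, Fourier retrieval — for a random-sphere lung phantom,
and fits the exponential thickness law

    −log df = (2π² d²/p₂²) · ε · t,     df = v_obj / v_ref,

where v is the fringe visibility per pixel, d the G1–G2 distance, p₂ the
fringe/analyzer pitch, and t the lung thickness along the beam.

It is aimed at researchers designing or evaluating dark-field systems who
need a controllable, reproducible forward model of the DF lung signal.

## Worked example

Two presets ship with the package: `murine` (small-animal scanner: 27.7 keV,
100 µm pixels, d = 4.47 cm, alveoli 39/60/80 µm, t = 1.8…10.8 mm) and
`human` (chest-radiography settings: 64.5 keV, 150 µm pixels, d = 10.4 cm,
alveoli 200/300/400 µm, t = 25…150 mm).

```python
import darkfield as df

cfg = df.apply_scale(df.load_preset("murine"), 8)   # desk scale: 2x2 px, 3 reps
series = df.run_thickness_series(
    cfg.geometry, cfg.detector, cfg.tissue, cfg.air,
    sphere_diameter=60e-6, thicknesses=cfg.thicknesses,
    n_repetitions=3, base_seed=10,
)
print(series.mean_df.round(4))
fit = df.fit_epsilon(series, cfg.geometry)
print(fit.summary())
```

prints (a ~20 s run):

```
[0.808  0.6644 0.5534 0.4437 0.3458 0.3169]
Linear diffusion coefficient fit (-log df = 2 pi^2 d^2/p2^2 * eps * t)
  preset            : custom
  sphere diameter   : 60 um
  epsilon           : 1.131e-11 1/mm
  std. error        : 2.2e-13 1/mm
  r-squared         : 0.99814
  slope factor      : 9.8527e+09
  intercept (diag.) : 2.029e-02 +/- 3.7e-02
```

The dark-field signal of a 60 µm-alveoli murine lung decays from 0.81 at
1.8 mm to 0.32 at 10.8 mm of lung; the fitted ε ≈ 1.1·10⁻¹¹ mm⁻¹ is the
material's scattering strength per unit thickness for this interferometer
geometry (at the full 16-samples-per-period sampling the same study yields
ε ≈ 1.31·10⁻¹¹ mm⁻¹; the quick `--scale 8` run trades some discretization
accuracy for speed).  Running the same at the `human` preset (300 µm
spheres) gives ε ≈ 1·10⁻¹³ mm⁻¹ — about 120× smaller — yet, because a
human thorax is ~15× thicker, the human DF signal at maximum thickness
(~0.4–0.47) remains in a usable range: dark-field chest radiography is not
washed out.

The same studies are available from the shell:

```bash
darkfield series  --preset murine --diameter 60 --scale 8 --seed 10 --out out/
darkfield compare --scale 8 --out out/        # murine vs human, eps ratio
darkfield simulate --preset murine --thickness 10.8 --out out/   # TIFF images
darkfield validate --scale 8                  # quick self-checks
```

Every output CSV embeds the fully resolved configuration, and a YAML
sidecar is written next to it, so any run can be reproduced bit-identically
from its own outputs (noise off).

See `docs/methods.md` for the model, its assumptions, the phantom
projection semantics, and known limitations.

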