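# paquant

Quantitative analysis of multi-wavelength photoacoustic (PA) images in the
presence of an exogenous near-infrared contrast agent: an indocyanine green
(ICG) J-aggregate probe whose narrow ~890 nm absorption band sits where the
hemoglobin spectra are flat, so it can be unmixed from blood without
corrupting oxygen-saturation estimates.

The package is aimed at researchers processing reconstructed multispectral
optoacoustic tomography stacks (ring-illumination small-animal systems) and
at anyone who wants a fully synthetic, ground-truth-controlled testbed for
PA spectral unmixing pipelines.

## What it computes

PA amplitude at a voxel follows `PA(x, λ) = Γ Φ(x, λ) μ_a(x, λ)`. The
pipeline:

1. **Spectral models** (`paquant.spectra`) — tabulated HbO₂/HHb molar
   extinction curves and parametric skew-normal bands for monomeric ICG
   (790 nm in water, 810 nm serum-bound) and the J-aggregate probe
   (890 nm peak, 30% of the monomer FWHM, 3× its peak extinction at
   equimolar dye).
2. **Synthetic data** (`paquant.simulate`) — tube phantoms (blood at
   parameterized SO₂, 10% v/v, co-mixed with probe at stated optical
   densities), longitudinal multi-organ studies with prescribed
   contrast-enhancement ground truth, serial dilutions, and exponential
   washout series; all seeded and returning their ground truth.
3. **Fluence correction** (`paquant.fluence`) — the ring-geometry surface
   fluence (water attenuation × photon-diffusion Green's functions)
   propagated into the body by solving `−∇·(D∇Φ) + μ_a Φ = 0` with
   Dirichlet surface data, then divided out of the stack.
4. **Spectral unmixing** (`paquant.unmixing`) — per-voxel linear
   regression onto {HbO₂, HHb, probe}; SO₂ image `HbO₂/(HbO₂+HHb)`,
   probe-fraction image `probe/(HbO₂+HHb+probe)`, automatic 3×3 tube
   ROIs, and cost functions that rank wavelength subsets (error terms plus
   a modest `α√N` penalty).
5. **Quantification** (`paquant.quantify`) — contrast enhancement
   `CE = (probe_post − probe_pre)/probe_pre` with a baseline-variation
   filter (voxels within mean ± SD of adjacent-slice preinjection
   differences are excluded), circulation half-life fits
   `PA(t) = PA₀ e^(−λt)`, `t½ = ln 2/λ`, Pearson spectral correlations,
   loading arithmetic and two-sample t-tests.
6. **I/O + workflows + CLI** (`paquant.io`, `paquant.workflows`,
   `paquant.cli`) — NIfTI-1/TIFF stacks with JSON sidecars, YAML run
   configs, two end-to-end workflows, and a `paquant` command with verbs
   `simulate-phantom`, `simulate-study`, `fluence-correct`, `unmix`,
   `select-wavelengths`, `quantify-ce`, `fit-halflife`, `run-phantom`,
   `run-study`.

## Worked example

```python
import numpy as np
from paquant import (default_library, make_phantom_scene, render_stack,
                     build_design, SpectralUnmixingModel, auto_tube_roi,
                     roi_scalar, derive_ratio_images, NoiseSpec)

lib = default_library()
scene = make_phantom_scene(so2=0.7, probe_od=0.9)        # blood + probe tube
stack = render_stack(scene, [710, 734, 760, 800, 830, 870],
                     noise=NoiseSpec(0.05, 0.0), seed=1)
design = build_design(lib, [710, 734, 760, 800, 830, 870],
                      ["hbo2", "hhb", "patrace"])
result = SpectralUnmixingModel(stack, design).fit()
roi = auto_tube_roi(stack)                               # 3x3 on the 800 nm max
so2_img, frac_img = derive_ratio_images(result, "patrace")
print(f"SO2 estimate: {roi_scalar(so2_img, roi):.3f}")
print(result.summary())
```

Output:

```
SO2 estimate: 0.696
Spectral unmixing (per-voxel ordinary least squares)
  wavelengths (nm) : [710.0, 734.0, 760.0, 800.0, 830.0, 870.0]
  chromophores     : ['hbo2', 'hhb', 'patrace']
  condition number : 252
  grid             : (12, 200, 200)
  median residual  : 2.4
  hbo2              : mean 0.005572, max 0.04324
  hhb               : mean 0.003811, max 0.01905
  patrace           : mean -5.423e-06, max 0.0004715
```

The SO₂ estimate recovers the prescribed 70% saturation to within the
noise floor (exactly, if `NoiseSpec(0, 0)` is used); the condition number
quantifies how separable the probe is from hemoglobin on this wavelength
set — swapping in monomeric ICG raises it.

Circulation half-life from a washout series:

```python
from paquant import make_decay_series, ExponentialDecayModel
s = make_decay_series(pa0=1.0, half_life_min=10.0,
                      times_min=np.linspace(0, 15, 46), noise_sd=0.02, seed=1)
print(ExponentialDecayModel(s.times_min, s.values).fit().summary())
```

```
Exponential decay fit (nonlinear least squares)
  PA0        : 1.005 +/- 0.0066
  lambda     : 0.0705 min^-1 +/- 0.001
  t_1/2      : 9.831 min (95% CI 9.547-10.12)
  residual   : 0.1206 over 46 samples
```

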