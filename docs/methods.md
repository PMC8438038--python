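# Methods

This note documents the models implemented in `paquant`, their defaults,
the synthetic-data generator's assumptions, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Chromophore spectral models

**Hemoglobin.** Oxy- and deoxyhemoglobin molar extinction (cm⁻¹ M⁻¹ per
heme) are packaged as a CSV tabulation on a 10 nm grid over 650–1000 nm,
linearly interpolated in between. The file is a *synthetic reconstruction*
of the standard compiled literature curves (see its header): it reproduces
the features every computation here depends on — the HHb band near 760 nm,
the isosbestic point near 797 nm, HbO₂ > HHb above 800 nm, and the flat
region of both species over 870–920 nm — but it is not digitised laboratory
data. Conclusions drawn from it are structural (rank, conditioning,
recovery identities), not metrological.

**Probe bands.** Monomeric ICG and the J-aggregate band are skew-normal
peaks. A band is parameterised by the quantities that are actually
constrained experimentally — peak wavelength, FWHM, peak molar extinction
and a shape (skew) parameter — and the underlying location/scale/amplitude
are solved numerically at load so that the mode, FWHM and maximum are hit
*exactly*. Parameters live in `data/probe_models.yaml`:

| model | peak (nm) | FWHM (nm) | peak ε (cm⁻¹ M⁻¹) |
|---|---|---|---|
| ICG monomer, water | 790 | 100 | 176 470.59 |
| ICG monomer, serum-bound | 810 | 100 | 176 470.59 |
| J-aggregate probe | 890 (880–890 between batches) | 30 | 529 411.76 |

The calibration anchor is the equimolar-OD equivalence: the J-aggregate
formulation reads 0.9 OD (1 cm path) at 1.7 µM dye, so its peak extinction
is 0.9/1.7 × 10⁶ = 529 411.76; the monomer's is one third of that
(threefold intensification on aggregation) and its FWHM is 10/3 of the
aggregate's (30% narrowing). The skew of −2 puts the residual tail on the
short-wavelength side, as for a J-band with a monomer shoulder. The exact
band asymmetry of the real agent is unknown; the parametric model is a
stand-in constrained by peak/width/amplitude only. The OD convention is
fixed at a 1 cm reference path throughout.

`peak_and_fwhm` refuses grids coarser than 1 nm (reproducibility of the
half-maximum crossings over smoothness); the peak is refined parabolically
through the three nodes around the discrete maximum.

## Synthetic-data generator

The generator emulates *reconstructed* image stacks; acoustic propagation,
transducer bandwidth and tomographic reconstruction artifacts are outside
its scope, as is concentration-dependent self-aggregation of monomeric ICG
at very high OD. What passing tests show, therefore, is that the analysis
chain is exact and robust for data that obey the linear PA forward model —
not that it is immune to reconstruction artifacts in real acquisitions.

**Forward model.** `PA = Γ Φ μₐ` per voxel and wavelength, with Γ = 1 by
default and Φ uniform unless a fluence field is supplied. μₐ is assembled
from the spectral library: heme molarity × blood spectrum + probe molarity
× probe spectrum, with probe OD maps converted through the peak extinction.
Constant background optics (μₐ = 10 m⁻¹, μs′ = 100 m⁻¹) apply to
chromophore-free voxels only: a voxel is either described by the
three-chromophore model or by the background, never both, which is what
makes noiseless end-to-end recovery exact (the closure every generator
guarantees).

**Phantom geometry.** A 2 cm gelatin cylinder with a 0.4 mm-inner-diameter
centered tube on a 200×200 grid at 0.1 mm spacing, 12 slices (multi-slice
2-D, not a meshed 3-D body). The tube is anti-aliased: sub-voxel coverage
(15× oversampling) scales the blood/probe content of edge voxels, the
partial-volume effect of an inclusion comparable to the voxel size. Because
SO₂ and the probe fraction are ratios, coverage scaling cancels and every
tube voxel still unmixes to the exact truth. Whole blood is 2.3 mM heme
(150 g/L hemoglobin), diluted to 10% v/v in the tube by default.

**Noise.** Multiplicative Gaussian (laser pulse-energy fluctuation,
σₘ = 0.05 default) plus an additive Gaussian floor (σₐ = 0.5% of the
noiseless stack maximum). Instrument noise levels are not otherwise
constrained; these defaults are the package's calibrated choice and all
robustness statements are relative to them. All randomness flows through
one seeded `numpy` generator recorded in stack provenance; identical seeds
give bitwise-identical stacks.

**Spectral coloring.** Real in-vessel light attenuation biases unmixing; a
perfectly matched noiseless forward model unmixes exactly, so the generator
exposes one knob to reproduce the bias: blood-containing voxels are
attenuated by `exp(−μₐ(λ) d_eff)` with an effective self-filtering depth
d_eff = 0.2 mm. This is the mechanism behind the documented ordering
(monomeric ICG suffers a larger SO₂ error and a larger deficit in the
recovered threefold concentration step than the J-aggregate probe).

**Longitudinal studies.** An elliptical body with disjoint liver, spleen,
kidney and tumor ROIs sharing slice positions across time-points
(co-registered by construction). Contrast enhancement is a *relative*
change of the probe-fraction image, so a clean preinjection animal (probe
fraction identically zero) would make CE undefined; each ROI therefore
starts from a baseline probe fraction f₀ = 0.1 and the generator sets the
probe concentration at time t so the noiseless fraction is exactly
f₀(1 + CE). Organ blood content and SO₂ (liver 70%, spleen 75%, kidney
80%, tumor 55%, on 5–30% of whole-blood heme) are nominal physiological
values; they serve as ground truth, not as physiology claims.

## Fluence model

Surface values at each boundary voxel are the superposition over the ring
sources (5 fiber-bundle pairs, 40 mm ring radius by default) of
`exp(−μa_water(λ) d) · exp(−μ_eff d)/(4π D d)` with d the straight-line
source-to-surface distance through the coupling bath; the pure-water
absorption curve is a packaged synthetic reconstruction of the standard
near-infrared water spectrum. Values are normalized to max 1 per
wavelength — the Green's-function normalization is arbitrary here since
only the spatial *shape* is divided out.

The interior solve is a finite-difference discretisation of
`−∇·(D∇Φ) + μₐΦ = 0` per slice with Dirichlet data on the extracted
surface (body voxels with an outside 4-neighbor), replacing a triangular
finite-element mesh with the identical mathematical object on the voxel
grid; one sparse LU per distinct slice mask is reused across wavelengths
because tissue optics are held constant across wavelength (only the water
term varies). The solver is validated against the closed-form disk
solution `I₀(μ_eff r)/I₀(μ_eff R)` (within 2% at 0.1 mm) and obeys the
discrete maximum principle. Division uses a floor of 5% of the field
maximum to prevent boundary blow-up; the correction flag toggles exactly
once per pipeline run.

## Unmixing and wavelength scoring

Per-voxel ordinary least squares (pinv of the design matrix) by default,
with an optional nonnegative variant (active-set NNLS per voxel, much
slower). Negative coefficients are clipped only when forming ratio images;
zero-denominator voxels become NaN (invalid ≠ zero) and are excluded from
ROI means. Automatic tube ROIs take the per-slice argmax of the 800 nm
image with row-major first-occurrence tie-breaking and a 3×3 window,
clipped with a warning at image borders.

The two cost functions combine their components with equal unit weights
plus a penalty α√N on the subset size; the component lists and the
square-root form are fixed, the combination rule and α = 0.01 are this
package's documented choice (α is "modest": it never overrides a
≥5-percentage-point error difference, and it lives in config). Subset
selection enumerates exhaustively (≤12 candidates), which keeps the search
deterministic and exactly reproducible.

## Quantification

Baseline variation pools voxel-wise differences of *all* consecutive
preinjection slice pairs within the ROI (the pair count is not otherwise
specified; pooling is the package's choice) and excludes CE values in the
closed interval [mean − SD, mean + SD]. On Gaussian noise this removes the
≈68.3% core without biasing the surviving mean. A fully-excluded ROI is
reported by the workflow as CE = 0 with zero survivors (no detectable
enhancement) rather than an error.

Half-life fits run in linear space by default (matching additive
measurement noise), with a log-linear option; the time origin is re-based
to the sample of maximum amplitude and at least 4 post-peak samples are
required. The 95% CI on t½ comes from the fit covariance by the delta
method. `half_life × λ = ln 2` holds to machine precision by construction.

The CE denominator guard is machine-epsilon-scaled to the preinjection
image maximum; such voxels are invalid, not infinite.

## Problem sizes

Default grids (200×200 at 0.1 mm, 12 slices) run the full four-combination,
100-seed phantom robustness study in about a minute on one CPU; property
checks that repeat simulations over many seeds use 1–3 slices and/or
120×120 grids, which leaves every per-voxel identity unchanged (slices are
i.i.d. replicas) while keeping the suite fast.

## Known limitations

- The hemoglobin and water tables are labelled synthetic reconstructions;
  absolute extinction values should not be quoted from this package.
- No acoustic/reconstruction modeling; no local (interior) spectral fluence
  correction — only the surface correction with wavelength-independent
  tissue optics is implemented.
- The probe band shape beyond peak/FWHM/amplitude/skew is unconstrained.
- The nonnegative unmixing path loops per voxel and is intended for ROIs,
  not whole volumes.
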