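# Parametric near-infrared probe absorption models.
#
# Each entry defines a skew-normal absorption band re-parameterised by the
# quantities that are actually constrained experimentally: the wavelength of
# maximum absorbance (peak_nm), the full width at half maximum (fwhm_nm) and
# the peak molar extinction per dye molecule (peak_eps, cm^-1 M^-1). The
# skew parameter sets band asymmetry (negative = tail toward shorter
# wavelengths, as for a J-aggregate band with a residual monomer shoulder).
#
# Calibration: the J-aggregate formulation reads 0.9 OD (1 cm path) at
# 1.7 uM dye at its own peak => peak_eps = 0.9 / 1.7e-6 = 529411.76.
# The monomer peak extinction is one third of that (the aggregate band is
# ~3-fold more intense at equimolar dye), and the aggregate FWHM is 30% of
# the monomer FWHM. The monomer peak sits at 790 nm in water and shifts to
# 810 nm when bound to serum albumin.
icg_monomer_water:
  peak_nm: 790.0
  fwhm_nm: 100.0
  peak_eps: 176470.59
  skew: -2.0
icg_monomer_serum:
  peak_nm: 810.0
  fwhm_nm: 100.0
  peak_eps: 176470.59
  skew: -2.0
patrace:
  peak_nm: 890.0        # batch-to-batch range 880-890 nm
  peak_nm_range: [880.0, 890.0]
  fwhm_nm: 30.0         # 0.30 x monomer FWHM
  peak_eps: 529411.76   # 3 x monomer peak; 0.9 OD at 1.7 uM
  skew: -2.0
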