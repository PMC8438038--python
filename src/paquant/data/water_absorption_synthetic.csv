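# name=water_absorption
# units=absorption coefficient of pure water, cm^-1
# source=synthetic
# version=1
# Synthetic reconstruction of the near-infrared pure-water absorption curve
# (Hale & Querry / Segelstein-style shape): low absorption below 700 nm, the
# shoulder near 740-760 nm, a minimum near 800 nm, and the steep rise toward
# the ~970 nm water band. Used only to weight source-to-surface attenuation
# in the coupling bath; NOT digitised laboratory data.
wavelength_nm,mua_cm
650,0.0032
660,0.0036
670,0.0042
680,0.0050
690,0.0057
700,0.0066
710,0.0095
720,0.0130
730,0.0190
740,0.0265
750,0.0270
760,0.0258
770,0.0244
780,0.0232
790,0.0218
800,0.0206
810,0.0216
820,0.0250
830,0.0290
840,0.0345
850,0.0410
860,0.0470
870,0.0520
880,0.0560
890,0.0605
900,0.0670
910,0.0780
920,0.1070
930,0.1600
940,0.2670
950,0.3200
960,0.3900
970,0.4500
980,0.4300
990,0.4000
1000,0.3630
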