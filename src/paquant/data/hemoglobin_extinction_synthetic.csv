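# name=hemoglobin_extinction
# units=molar extinction coefficient, cm^-1 M^-1 (per heme)
# source=synthetic
# version=1
# Synthetic reconstruction of the standard compiled human hemoglobin molar
# extinction curves (the widely used Prahl/OMLC-style compilation of the
# Moaveni / Takatani-Graham / Zijlstra measurements). Values were written to
# reproduce the qualitative features that drive every computation in this
# package: the HHb band near 760 nm, the isosbestic point near 797 nm, the
# crossover of HbO2 above HHb beyond 800 nm, and the relatively flat spectra
# of both species over 870-920 nm. They are NOT digitised laboratory data.
wavelength_nm,hbo2,hhb
650,368,3750
660,320,3227
670,294,2795
680,277,2408
690,276,2052
700,290,1794
710,314,1540
720,348,1328
730,390,1102
740,446,1116
750,532,1405
760,586,1549
770,650,1312
780,710,1075
790,774,891
800,816,762
810,864,717
820,916,694
830,974,693
840,1022,692
850,1058,691
860,1104,694
870,1138,700
880,1168,711
890,1188,724
900,1198,762
910,1210,787
920,1206,816
930,1196,834
940,1214,850
950,1204,885
960,1170,905
970,1140,925
980,1100,945
990,1080,965
1000,1058,986
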