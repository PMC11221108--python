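# Specific absorption factors of oxy- and deoxy-hemoglobin at the two
# operating wavelengths, expressed so that
#
#     mua [1/cm] = factor [1/cm per uM] * concentration [uM]
#
# The factors are pre-multiplied: molar extinction coefficients e
# [1/cm per mol/l, decadic] from the standard Gratzer/Prahl compilation of
# hemoglobin absorption spectra, converted as factor = ln(10) * e * 1e-6.
# Source molar extinction values (1/cm/M):
#   690 nm: O2Hb 276.0,  HHb 2051.96
#   830 nm: O2Hb 974.0,  HHb 693.04
extinction:
  690:
    o2hb: 6.35513e-04
    hhb: 4.72481e-03
  830:
    o2hb: 2.24272e-03
    hhb: 1.59578e-03
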