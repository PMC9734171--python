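"""Physical constants and tabulated hemoglobin optical properties.

Molar extinction coefficients are approximate values from the standard
tabulated compilation of oxy-/deoxyhemoglobin absorption spectra
(cm^-1 per mole/liter).  Their absolute scale cancels in the sO2 estimate;
only the ratio between the two wavelengths matters.
"""

#: Speed of light in vacuum (m/s).
C_LIGHT = 299_792_458.0

#: Speed of sound in water coupling medium (m/s).
C_SOUND = 1500.0

#: Molar extinction of oxyhemoglobin (cm^-1/M) at the two excitation lines.
EPS_HBO2 = {532e-9: 44_480.0, 558e-9: 27_630.0}

#: Molar extinction of deoxyhemoglobin (cm^-1/M).
EPS_HB = {532e-9: 40_584.0, 558e-9: 52_276.0}
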