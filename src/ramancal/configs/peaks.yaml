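# Stylized analyte band library (center/width in cm^-1, coeff in a.u. per g/L).
# Bands of different analytes partially overlap on purpose so that
# concentration estimation requires multivariate resolution, not a single
# isolated band.  Glutamate's coefficients are ~20x weaker than glucose's,
# making it the hard analyte.  The "matrix" block is the constant medium
# background (coeff in absolute a.u.): water bending (~1640) and O-H
# stretching (~3230) dominate total intensity, as in real aqueous
# cell-culture spectra.
analytes:
  glucose:
    - {center: 519, width: 11, shape: gaussian, coeff: 1.0}
    - {center: 912, width: 10, shape: gaussian, coeff: 0.45}
    - {center: 1065, width: 13, shape: gaussian, coeff: 0.85}
    - {center: 1127, width: 11, shape: gaussian, coeff: 0.9}
  lactate:
    - {center: 830, width: 11, shape: gaussian, coeff: 0.9}
    - {center: 1045, width: 13, shape: gaussian, coeff: 0.75}
    - {center: 1455, width: 15, shape: gaussian, coeff: 0.65}
  glutamine:
    - {center: 1090, width: 13, shape: gaussian, coeff: 0.55}
    - {center: 1410, width: 14, shape: gaussian, coeff: 0.6}
    - {center: 1670, width: 18, shape: lorentzian, coeff: 0.5}
  glutamate:
    - {center: 860, width: 11, shape: gaussian, coeff: 0.05}
    - {center: 1355, width: 13, shape: gaussian, coeff: 0.04}
    - {center: 1615, width: 15, shape: gaussian, coeff: 0.05}
matrix:
  - {center: 1003, width: 8, shape: gaussian, coeff: 180}
  - {center: 1450, width: 22, shape: gaussian, coeff: 240}
  - {center: 1640, width: 38, shape: gaussian, coeff: 720}
  - {center: 2935, width: 28, shape: gaussian, coeff: 420}
  - {center: 3230, width: 75, shape: gaussian, coeff: 1900}
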