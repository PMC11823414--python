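{
  "comment": "Hand-evaluated extended Stevens operator matrices from the standard operator-equivalent polynomials (X = J(J+1)); diagonal operators listed by descending m. Synthetic golden file: values computed by hand from the defining formulas, pinning the package's sign/normalization convention.",
  "O20_J1_diag": [1, -2, 1],
  "O40_J2_diag": [12, -48, 72, -48, 12],
  "O60_J3_diag": [180, -1080, 2700, -3600, 2700, -1080, 180],
  "O22_J1": [[0, 0, 1], [0, 0, 0], [1, 0, 0]],
  "O21_J1_entry_01": 0.35355339059327373,
  "O21_note": "O_2^1 = (1/4)[Jz(J+ + J-) + (J+ + J-)Jz]; for J=1 its (m=1, m=0) element is (1/4)(0+1)*sqrt(2) = sqrt(2)/4."
}
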