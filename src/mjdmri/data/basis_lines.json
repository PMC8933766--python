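{
  "comment": "Synthetic Lorentzian line catalogue for the default mouse cerebellum basis set. Chemical shifts (ppm) follow literature values for the major 1H resonances; amplitudes are relative proton weights and linewidths are half-widths at half-maximum in ppm, chosen for a well-conditioned synthetic basis rather than fitted to measured spectra. Substitute a measured basis via the basis-directory format for real data.",
  "default_linewidth_ppm": 0.035,
  "metabolites": {
    "NAA":  [[2.008, 3.0, null], [2.49, 1.0, null], [2.67, 1.0, null]],
    "NAAG": [[2.042, 3.0, null], [2.59, 1.0, null], [3.72, 1.0, null]],
    "Cr":   [[3.027, 3.0, null], [3.913, 2.0, null]],
    "PCr":  [[3.045, 3.0, null], [3.93, 2.0, null]],
    "Glu":  [[2.08, 2.0, null], [2.35, 2.0, null], [3.74, 1.0, null]],
    "Gln":  [[2.12, 2.0, null], [2.44, 2.0, null], [3.76, 1.0, null]],
    "Ins":  [[3.52, 4.0, null], [3.61, 2.0, null], [4.05, 1.0, null]],
    "Tau":  [[3.25, 2.0, null], [3.42, 2.0, null]],
    "Cho":  [[3.185, 9.0, null], [4.05, 2.0, null]],
    "PCh":  [[3.21, 9.0, null], [3.58, 1.0, null]],
    "GPC":  [[3.23, 9.0, null], [3.65, 1.0, null]],
    "GSH":  [[2.55, 2.0, null], [2.95, 2.0, null], [3.77, 1.0, null]],
    "GABA": [[1.89, 2.0, null], [2.28, 2.0, null], [3.01, 2.0, null]],
    "Lac":  [[1.31, 3.0, null], [4.10, 1.0, null]],
    "Ala":  [[1.47, 3.0, null], [3.78, 1.0, null]],
    "MM":   [[0.92, 3.0, 0.2], [1.21, 3.0, 0.2], [1.43, 2.0, 0.2], [2.05, 2.0, 0.2], [3.0, 2.0, 0.2]],
    "Lip":  [[0.89, 2.0, 0.09], [1.28, 6.0, 0.09]]
  }
}
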