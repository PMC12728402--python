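{
  "analyte": "RBP",
  "unit": "mg/L",
  "levels": [
    {"level": 1, "iqc_mean": 25.0, "iqc_cv": 6.97, "n_iqc": 180, "period": "2023-01-01/2023-07-01"},
    {"level": 2, "iqc_mean": 46.0, "iqc_cv": 3.27, "n_iqc": 180, "period": "2023-01-01/2023-07-01"}
  ],
  "eqa_biases": [3.0, -3.0, 3.0, -3.0, 3.0, -3.0],
  "u_cref": 0.0,
  "k": 2.0,
  "quality_goal": 16.0,
  "z_serial": 1.96
}
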