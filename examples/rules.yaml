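# Westgard rule configuration for `labqc iqc evaluate --rules rules.yaml`.
rules: ["1_2s", "1_3s", "2_2s", "R_4s", "4_1s", "10_x"]
windows:
  2_2s: 2
  4_1s: 4
  10_x: 10
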