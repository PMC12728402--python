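# EQA multirule configuration for `labqc eqa analyze --rules eqa_rules.yaml`.
rules: ["1_TEa", "1_75pTEa", "same_side", "2of3_2SDI", "R_range"]
min_same_side: 5
sdi_limit: 2.0
r_range_span: 4.0
tea_warning_fraction: 0.75
allow_unacceptable: false
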