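# Verdict tiers for `labqc interlab compare --thresholds tiers.yaml`.
# |SDI| <= sdi_acceptable -> acceptable; <= sdi_monitor -> monitor; else unacceptable.
sdi_acceptable: 1.25
sdi_monitor: 2.0
cvr_acceptable: 1.0
cvr_monitor: 1.5
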