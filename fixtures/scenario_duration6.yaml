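# overlay: treatment duration extended to 6 years
treatment_effects:
  treatment_duration_years: 6
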