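# Any malignancy (ICD-9-CM), used for the in-study exclusion.
name: malignancy
entries:
  - "140-208"
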