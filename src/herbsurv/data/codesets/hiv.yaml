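# HIV/AIDS case-defining diagnosis codes (ICD-9-CM).
name: hiv_aids
entries:
  - "042-044"
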