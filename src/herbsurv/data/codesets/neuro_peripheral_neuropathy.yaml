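# Peripheral neuropathy (ICD-9-CM). 352 is deliberately absent.
name: peripheral_neuropathy
entries:
  - "350"
  - "351"
  - "353"
  - "354"
  - "355"
  - "356"
  - "357"
  - "358"
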