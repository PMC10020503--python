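# Cognitive disorders (ICD-9-CM).
name: cognitive
entries:
  - "290"
  - "293"
  - "294"
  - "332"
  - "345"
  - "348.1"
  - "348.3"
  - "780.3"
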