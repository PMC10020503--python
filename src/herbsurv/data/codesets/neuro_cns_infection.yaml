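# CNS infections (ICD-9-CM).
name: cns_infection
entries:
  - "013"
  - "047"
  - "053"
  - "094"
  - "200"
  - "320"
  - "321"
  - "322"
  - "323"
  - "054.3"
  - "054.4"
  - "114.2"
  - "130.0"
  - "321.0"
  - "003.21"
  - "098.82"
  - "112.83"
  - "115.91"
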