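# Vasculopathy (ICD-9-CM).
name: vasculopathy
entries:
  - "325"
  - "430-437"
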