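# Six opportunistic-infection flags (ICD-9-CM code lists).
name: opportunistic_infections
sets:
  pjp:                 # Pneumocystis jirovecii pneumonia
    - "136.3"
  cmv:                 # cytomegalovirus disease (other than liver, spleen, or nodes)
    - "078.5"
    - "484.1"
  tb:                  # Mycobacterium tuberculosis
    - "010-012"
    - "018"
  candidiasis:         # candidiasis of esophagus, bronchi, trachea, lung
    - "112.4"
    - "112.84"
  cryptococcosis:      # cryptococcosis, extrapulmonary
    - "117.5"
    - "321.0"
  mac:                 # disseminated M. avium complex or M. kansasii
    - "031.2"
    - "031.9"
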