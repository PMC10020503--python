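# Cause-of-death categories mapped at ICD chapter level.  Order matters:
# the first matching category wins, so viral hepatitis / liver disease is
# listed before the infectious-disease chapter that contains code 070 / B15-B19.
name: cause_categories
categories:
  - label: hepatitis_liver
    icd9: ["070", "571-573"]
    icd10: ["B15-B19", "K70-K77"]
  - label: infections_parasites
    icd9: ["001-139"]
    icd10: ["A00-B99"]
  - label: circulatory
    icd9: ["390-459"]
    icd10: ["I00-I99"]
  - label: endocrine_metabolic
    icd9: ["240-279"]
    icd10: ["E00-E90"]
  - label: respiratory
    icd9: ["460-519"]
    icd10: ["J00-J99"]
  - label: genitourinary
    icd9: ["580-629"]
    icd10: ["N00-N99"]
  - label: neoplasms
    icd9: ["140-239"]
    icd10: ["C00-D48"]
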